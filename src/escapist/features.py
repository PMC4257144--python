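"""Learning phase: per-pair-type EPD statistics and the template they produce.

For every sequence-consecutive residue pair the electrostatic potential difference (EPD)
between a configured atom of the first residue and a configured atom of the second is
collected, keyed by the alphabetically sorted amino-acid type pair.  Sorting makes pairs
order-independent; when the observed order is the reverse of the sorted key the sign of
the difference is flipped (the ``multfactor``), so "CA" observations enter the "AC"
statistics with reversed sign.  Pair types whose standard deviation exceeds ``sdThresh``
(50 kT/e by default) are too loosely constrained to discriminate anything and are
dropped from the template; so are pairs with too few observations.
"""

from __future__ import annotations

import importlib.resources
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from escapist.electrostatics import (
    AtomPotentials,
    SolverParams,
    assign_charges_radii,
    atom_potentials,
)
from escapist.structure_io import (
    ProteinStructure,
    ResiduePairRef,
    consecutive_pairs,
    STANDARD_AA,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "PairKey",
    "EPDObservation",
    "EPDTemplate",
    "canonical_pair",
    "compute_epd",
    "learn_features",
    "epd_vs_distance",
    "write_template",
    "read_template",
    "packaged_template",
    "EmptyTemplateError",
    "TemplateParseError",
]


class EmptyTemplateError(ValueError):
    """Learning produced no observations at all."""


class TemplateParseError(ValueError):
    """A template file row could not be parsed; message names the line."""


@dataclass(frozen=True)
class FeatureConfig:
    """Settings of the learning and scoring phases.

    ``atomP``/``atomQ`` name the atoms read in the first and second residue of each
    pair: CB/CB (default, the discriminating sidechain proxy), CA/CA, or C/N for the
    peptide-bond profile.  Three N- and C-terminal residues are ignored by default to
    keep terminal charges out of the statistics.  ``sdThresh`` is in kT/e.
    """

    atomP: str = "CB"
    atomQ: str = "CB"
    ignoreNTerm: int = 3
    ignoreCTerm: int = 3
    sdThresh: float = 50.0
    minSamples: int = 30
    excludeCysteine: bool = False
    perProteinAveraging: bool = False

    def __post_init__(self) -> None:
        if self.sdThresh <= 0:
            raise ValueError("sdThresh must be > 0")
        if self.minSamples < 1:
            raise ValueError("minSamples must be >= 1")


@dataclass(frozen=True)
class PairKey:
    """Sorted two-letter amino-acid pair key and the sign flip its sorting implied."""

    key: str
    multfactor: int


def canonical_pair(typeA: str, typeB: str) -> PairKey:
    """Sorted pair key; ``multfactor`` is -1 when the observed order was swapped."""
    if typeA not in STANDARD_AA or typeB not in STANDARD_AA:
        raise ValueError(f"invalid residue code in pair ({typeA!r}, {typeB!r})")
    if typeB < typeA:
        return PairKey(key=typeB + typeA, multfactor=-1)
    return PairKey(key=typeA + typeB, multfactor=1)


@dataclass(frozen=True)
class EPDObservation:
    pairKey: str
    value: float  # canonical signed EPD, kT/e
    structureId: str
    pairRef: ResiduePairRef


def compute_epd(
    potentials: AtomPotentials,
    pair: ResiduePairRef,
    config: FeatureConfig,
    structureId: str = "",
) -> EPDObservation | None:
    """Canonical EPD of one consecutive pair, or None when an atom is missing.

    The raw difference is phi(atomP of residue n) - phi(atomQ of residue n+1), taken
    N-terminal to C-terminal, then multiplied by the canonicalization sign.  Glycine in
    C-beta mode (no CB atom) and residues with missing density are skipped with a log
    message rather than treated as errors.
    """
    phiP = potentials.get(pair.chainId, pair.n, config.atomP)
    phiQ = potentials.get(pair.chainId, pair.n + 1, config.atomQ)
    if phiP is None or phiQ is None:
        missing = config.atomP if phiP is None else config.atomQ
        logger.debug("skipping pair %s%d (%s%s): no %s atom potential",
                     pair.chainId, pair.n, pair.aaTypeFirst, pair.aaTypeSecond, missing)
        return None
    ck = canonical_pair(pair.aaTypeFirst, pair.aaTypeSecond)
    return EPDObservation(pairKey=ck.key, value=(phiP - phiQ) * ck.multfactor,
                          structureId=structureId, pairRef=pair)


@dataclass
class EPDTemplate:
    """The learned statistical potential: pair key -> (mean, sd, n) in kT/e."""

    mode: tuple[str, str]
    entries: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def mean(self, key: str) -> float | None:
        e = self.entries.get(key)
        return e[0] if e else None

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _potentials_for(structure: ProteinStructure, params: SolverParams | None,
                    backend) -> AtomPotentials:
    if callable(backend):
        return backend(structure)
    charged = assign_charges_radii(structure)
    return atom_potentials(charged, params, backend=backend)


def observations_for_structure(
    structure: ProteinStructure,
    config: FeatureConfig,
    backend="builtin",
    params: SolverParams | None = None,
) -> list[EPDObservation]:
    """All canonical EPD observations for one structure (one potential solve)."""
    potentials = _potentials_for(structure, params, backend)
    obs = []
    for pair in consecutive_pairs(structure, config.ignoreNTerm, config.ignoreCTerm):
        o = compute_epd(potentials, pair, config, structureId=structure.id)
        if o is not None:
            obs.append(o)
    return obs


def _mean_sd(values: list[float]) -> tuple[float, float]:
    m = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return m, sd


def learn_features(
    structures: Iterable[ProteinStructure],
    config: FeatureConfig | None = None,
    backend="builtin",
    params: SolverParams | None = None,
) -> EPDTemplate:
    """Build an EPD template from a set of (assumed native) structures.

    Observations are pooled across structures per pair type, then reduced to mean and
    sample standard deviation (n-1 denominator).  With ``config.perProteinAveraging``
    the mean is instead the unweighted average of per-structure means (the two agree
    when every structure contributes equally).  Entries with sd > ``sdThresh`` or fewer
    than ``minSamples`` observations are dropped; with ``excludeCysteine`` every
    cysteine-containing pair is dropped regardless of its spread.
    """
    config = config or FeatureConfig()
    pooled: dict[str, list[float]] = {}
    per_structure: dict[str, dict[str, list[float]]] = {}
    n_structures = 0
    for structure in structures:
        n_structures += 1
        for o in observations_for_structure(structure, config, backend, params):
            pooled.setdefault(o.pairKey, []).append(o.value)
            per_structure.setdefault(o.structureId, {}).setdefault(
                o.pairKey, []).append(o.value)
    if not pooled:
        raise EmptyTemplateError("no EPD observations could be extracted from the set")

    entries: dict[str, tuple[float, float, int]] = {}
    for key, values in sorted(pooled.items()):
        mean, sd = _mean_sd(values)
        if config.perProteinAveraging:
            per_means = [_mean_sd(d[key])[0]
                         for d in per_structure.values() if key in d]
            mean = statistics.fmean(per_means)
        if sd > config.sdThresh:
            continue
        if len(values) < config.minSamples:
            continue
        if config.excludeCysteine and "C" in key:
            continue
        entries[key] = (mean, sd, len(values))

    backend_name = backend if isinstance(backend, str) else "injected"
    return EPDTemplate(
        mode=(config.atomP, config.atomQ),
        entries=entries,
        provenance={
            "backend": backend_name,
            "n_structures": str(n_structures),
            "statistics": "per-protein-averaged" if config.perProteinAveraging else "pooled",
            "sdThresh": str(config.sdThresh),
            "minSamples": str(config.minSamples),
        },
    )


def epd_vs_distance(
    structures: Iterable[ProteinStructure],
    pairKeyWanted: str,
    maxDistance: int,
    config: FeatureConfig | None = None,
    backend="builtin",
    params: SolverParams | None = None,
) -> list[tuple[int, float, int]]:
    """SD of the EPD for one pair type as a function of sequence separation.

    For each separation d = 1..maxDistance, collects the canonical EPD between residue n
    and residue n+d restricted to ``pairKeyWanted``, and reports (d, sd, count).  Bins
    with fewer than ``config.minSamples`` observations are omitted.  A rising profile
    indicates that consecutive-residue EPDs are genuinely more constrained than distant
    ones; a flat profile is what uncorrelated per-atom potentials produce.
    """
    if maxDistance < 1:
        raise ValueError("maxDistance must be >= 1")
    config = config or FeatureConfig()
    bins: dict[int, list[float]] = {d: [] for d in range(1, maxDistance + 1)}
    for structure in structures:
        potentials = _potentials_for(structure, params, backend)
        for chain in structure.chains:
            N = len(chain)
            for d in range(1, maxDistance + 1):
                lo = 1 + config.ignoreNTerm
                hi = N - config.ignoreCTerm - d  # 1-based position of first residue
                for p in range(lo, hi + 1):
                    r1 = chain.residues[p - 1]
                    r2 = chain.residues[p - 1 + d]
                    if r2.seqIndex - r1.seqIndex != d:
                        continue
                    ck = canonical_pair(r1.aaType, r2.aaType)
                    if ck.key != pairKeyWanted:
                        continue
                    phiP = potentials.get(r1.chainId, r1.seqIndex, config.atomP)
                    phiQ = potentials.get(r2.chainId, r2.seqIndex, config.atomQ)
                    if phiP is None or phiQ is None:
                        continue
                    bins[d].append((phiP - phiQ) * ck.multfactor)
    out = []
    for d in range(1, maxDistance + 1):
        values = bins[d]
        if len(values) < config.minSamples:
            continue
        _, sd = _mean_sd(values)
        out.append((d, sd, len(values)))
    return out


# ---------------------------------------------------------------------------
# Template I/O
# ---------------------------------------------------------------------------


def write_template(template: EPDTemplate, path: str | Path) -> None:
    """Write a template as TSV: provenance comments, then PAIR/MEAN/SD/N columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mode\t{template.mode[0]}\t{template.mode[1]}\n")
        for k, v in template.provenance.items():
            fh.write(f"# {k}\t{v}\n")
        fh.write("PAIR\tMEAN\tSD\tN\n")
        for key in sorted(template.entries):
            mean, sd, n = template.entries[key]
            fh.write(f"{key}\t{mean:.10g}\t{sd:.10g}\t{n}\n")


def read_template(path: str | Path) -> EPDTemplate:
    """Read a template TSV written by :func:`write_template` (or hand-authored)."""
    path = Path(path)
    mode = ("CB", "CB")
    provenance: dict[str, str] = {}
    entries: dict[str, tuple[float, float, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip():
                continue
            if s.startswith("#"):
                parts = s.lstrip("# ").split("\t")
                if parts[0] == "mode" and len(parts) == 3:
                    mode = (parts[1], parts[2])
                elif len(parts) == 2:
                    provenance[parts[0]] = parts[1]
                continue
            fields = s.split("\t")
            if fields[0] == "PAIR":
                continue
            if len(fields) != 4:
                raise TemplateParseError(f"{path}: line {lineno}: expected 4 columns")
            key = fields[0].strip()
            try:
                mean, sd, n = float(fields[1]), float(fields[2]), int(fields[3])
            except ValueError as exc:
                raise TemplateParseError(f"{path}: line {lineno}: {exc}") from exc
            if len(key) != 2 or any(c not in STANDARD_AA for c in key):
                raise TemplateParseError(f"{path}: line {lineno}: bad pair key {key!r}")
            if key[0] > key[1]:
                logger.warning("%s: line %d: unsorted pair key %s normalized",
                               path, lineno, key)
                key = key[1] + key[0]
            entries[key] = (mean, sd, n)
    return EPDTemplate(mode=mode, entries=entries, provenance=provenance)


def packaged_template(name: str = "published_cbeta_template.tsv") -> EPDTemplate:
    """Load a template shipped with the package (default: the published 16-pair
    C-beta excerpt of the reference learned set)."""
    resource = importlib.resources.files("escapist.data") / name
    with importlib.resources.as_file(resource) as p:
        return read_template(p)
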