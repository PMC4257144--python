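"""Quality-assessment phase: the PDscore and decoy-set evaluation.

The PDscore of a structure is the mean absolute deviation of its observed consecutive-
residue EPDs from the learned template means, taken only over pairs whose type survives
the template's SD filter (the normalization divides by the number actually compared, so
skipped pairs -- glycine in C-beta mode, filtered pair types, chain breaks -- do not
dilute the score).  The working hypothesis, following the Boltzmann view of structure
databases and the thermodynamic hypothesis that the native state minimizes free energy,
is that the native structure minimizes the PDscore within a set of candidate models.

Specificity of a decoy set for one target is the fraction of decoys scored strictly
worse (higher) than the native; ties count against the native.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from escapist.electrostatics import SolverParams, assign_charges_radii, atom_potentials
from escapist.features import EPDTemplate, FeatureConfig, canonical_pair, compute_epd
from escapist.structure_io import (
    ProteinStructure,
    ResiduePairRef,
    StructureParseError,
    EmptyStructureError,
    consecutive_pairs,
    parse_structure,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PDScoreResult",
    "DecoyEvaluation",
    "PairContribution",
    "pd_score",
    "rank_decoys",
    "evaluate_decoy_set",
    "UnscorableStructureError",
    "DecoyLayoutError",
]


class UnscorableStructureError(ValueError):
    """No consecutive pair of the structure has a template entry (distinct from score 0)."""


class DecoyLayoutError(ValueError):
    """A decoy-set directory does not match the expected layout; message names the path."""


@dataclass(frozen=True)
class PairContribution:
    pairRef: ResiduePairRef
    pairKey: str
    observedEPD: float
    templateMean: float
    absDiff: float


@dataclass
class PDScoreResult:
    """Normalized deviation score for one structure: lower is more native-like."""

    pdscore: float
    numberCompared: int
    contributions: list[PairContribution] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pdscore": self.pdscore,
            "numberCompared": self.numberCompared,
            "contributions": [
                {
                    "chain": c.pairRef.chainId,
                    "n": c.pairRef.n,
                    "pair": c.pairKey,
                    "observedEPD": c.observedEPD,
                    "templateMean": c.templateMean,
                    "absDiff": c.absDiff,
                }
                for c in self.contributions
            ],
        }


def pd_score(
    structure: ProteinStructure,
    template: EPDTemplate,
    config: FeatureConfig | None = None,
    backend="builtin",
    params: SolverParams | None = None,
    first_chain_only: bool = False,
) -> PDScoreResult:
    """Score one structure against a learned template.

    For each consecutive residue pair with a template entry the absolute deviation of
    the observed canonical EPD from the learned mean is accumulated; the final score is
    that sum divided by the number of pairs actually compared.  Multi-chain structures
    are scored over all chains unless ``first_chain_only`` is set.

    Raises :class:`UnscorableStructureError` when no pair could be compared.
    """
    config = config or FeatureConfig()
    if (config.atomP, config.atomQ) != template.mode:
        raise ValueError(
            f"template mode {template.mode} does not match config "
            f"({config.atomP}, {config.atomQ})")
    if first_chain_only and len(structure.chains) > 1:
        structure = ProteinStructure(id=structure.id, chains=structure.chains[:1])

    if callable(backend):
        potentials = backend(structure)
    else:
        charged = assign_charges_radii(structure)
        potentials = atom_potentials(charged, params, backend=backend)

    total = 0.0
    contributions: list[PairContribution] = []
    for pair in consecutive_pairs(structure, config.ignoreNTerm, config.ignoreCTerm):
        key = canonical_pair(pair.aaTypeFirst, pair.aaTypeSecond).key
        mean = template.mean(key)
        if mean is None:
            continue
        obs = compute_epd(potentials, pair, config, structureId=structure.id)
        if obs is None:
            continue
        diff = abs(obs.value - mean)
        total += diff
        contributions.append(PairContribution(
            pairRef=pair, pairKey=key, observedEPD=obs.value,
            templateMean=mean, absDiff=diff))
    if not contributions:
        raise UnscorableStructureError(
            f"structure {structure.id}: no consecutive pair has a template entry")
    return PDScoreResult(
        pdscore=total / len(contributions),
        numberCompared=len(contributions),
        contributions=contributions,
    )


@dataclass
class DecoyEvaluation:
    """Native and decoy scores for one target, with the resulting specificity."""

    targetId: str
    nativeScore: PDScoreResult
    decoyScores: dict[str, PDScoreResult]
    warnings: int = 0
    nResidues: int = 0

    @property
    def specificity(self) -> float:
        worse = sum(1 for r in self.decoyScores.values()
                    if r.pdscore > self.nativeScore.pdscore)
        return worse / len(self.decoyScores)

    @property
    def native_rank(self) -> int:
        """1-based rank of the native among all scored structures (ties rank worst)."""
        return 1 + sum(1 for r in self.decoyScores.values()
                       if r.pdscore <= self.nativeScore.pdscore)


def rank_decoys(
    native: PDScoreResult,
    decoys: dict[str, PDScoreResult],
    targetId: str = "",
) -> DecoyEvaluation:
    """Specificity of a scored decoy set: fraction of decoys strictly worse than native.

    A decoy tying the native counts against the native (the score failed to separate
    them), so a single-decoy target yields specificity 1 or 0.
    """
    if not decoys:
        raise ValueError(f"target {targetId or '?'}: no decoys to rank")
    return DecoyEvaluation(targetId=targetId, nativeScore=native, decoyScores=dict(decoys))


# ---------------------------------------------------------------------------
# Decoy-set directory evaluation
# ---------------------------------------------------------------------------


def _discover_target(target_dir: Path) -> tuple[Path, list[Path]]:
    """Locate the native and decoy files in one target directory.

    Supported layouts (checked in order):
      * a ``list`` file whose first entry is the native (classic decoy-database style);
      * ``correct.pdb`` + ``incorrect*.pdb`` (misfold-style pairs; the first incorrect
        file in sorted order is taken when there are several);
      * ``native.pdb`` plus every other ``*.pdb`` as decoys.
    """
    list_file = target_dir / "list"
    if list_file.exists():
        names = [ln.strip() for ln in list_file.read_text().splitlines() if ln.strip()]
        paths = [target_dir / n for n in names]
        missing = [p for p in paths if not p.exists()]
        if missing or len(paths) < 2:
            raise DecoyLayoutError(f"{target_dir}: bad list file (missing {missing})")
        return paths[0], paths[1:]
    correct = target_dir / "correct.pdb"
    if correct.exists():
        incorrect = sorted(target_dir.glob("incorrect*.pdb"))
        if not incorrect:
            raise DecoyLayoutError(f"{target_dir}: correct.pdb without incorrect*.pdb")
        return correct, incorrect[:1]
    native = target_dir / "native.pdb"
    if native.exists():
        decoys = sorted(p for p in target_dir.glob("*.pdb") if p.name != "native.pdb")
        if not decoys:
            raise DecoyLayoutError(f"{target_dir}: native.pdb but no decoy files")
        return native, decoys
    raise DecoyLayoutError(f"{target_dir}: no list file, correct.pdb or native.pdb found")


def evaluate_decoy_set(
    root: str | Path,
    template: EPDTemplate,
    config: FeatureConfig | None = None,
    backend="builtin",
    params: SolverParams | None = None,
) -> tuple[list[DecoyEvaluation], dict]:
    """Score every target directory under ``root`` and aggregate specificities.

    Each immediate subdirectory of ``root`` is one target.  Structures that fail to
    parse or score are excluded with a logged warning (and counted); the aggregate
    report carries per-target specificity and the unweighted mean across targets.
    """
    root = Path(root)
    if not root.is_dir():
        raise DecoyLayoutError(f"decoy root {root} is not a directory")
    target_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not target_dirs:
        raise DecoyLayoutError(f"decoy root {root} contains no target directories")

    evaluations: list[DecoyEvaluation] = []
    for tdir in target_dirs:
        native_path, decoy_paths = _discover_target(tdir)
        try:
            native_structure = parse_structure(native_path)
            native = pd_score(native_structure, template, config, backend, params)
        except (StructureParseError, EmptyStructureError, UnscorableStructureError) as exc:
            logger.warning("target %s: native unscorable, skipping target (%s)",
                           tdir.name, exc)
            continue
        decoys: dict[str, PDScoreResult] = {}
        warnings = 0
        for dp in decoy_paths:
            try:
                decoys[dp.stem] = pd_score(parse_structure(dp), template,
                                           config, backend, params)
            except (StructureParseError, EmptyStructureError,
                    UnscorableStructureError) as exc:
                warnings += 1
                logger.warning("target %s: decoy %s excluded (%s)", tdir.name,
                               dp.name, exc)
        if not decoys:
            logger.warning("target %s: no scorable decoys, skipping target", tdir.name)
            continue
        ev = rank_decoys(native, decoys, targetId=tdir.name)
        ev.warnings = warnings
        ev.nResidues = native_structure.n_residues
        evaluations.append(ev)

    if not evaluations:
        raise DecoyLayoutError(f"decoy root {root}: no target could be evaluated")
    report = aggregate_report(evaluations)
    return evaluations, report


def aggregate_report(evaluations: list[DecoyEvaluation]) -> dict:
    per_target = [
        {
            "PDB": ev.targetId,
            "NRes": ev.nResidues,
            "NStructures": len(ev.decoyScores) + 1,
            "NativeScore": ev.nativeScore.pdscore,
            "Specificity": ev.specificity,
            "Warnings": ev.warnings,
        }
        for ev in evaluations
    ]
    mean_spec = sum(t["Specificity"] for t in per_target) / len(per_target)
    return {"targets": per_target, "mean_specificity": mean_spec}


def write_report(report: dict, tsv_path: str | Path | None = None,
                 json_path: str | Path | None = None) -> None:
    """Write the aggregate report: TSV mirroring the benchmark-table columns, and/or
    a JSON document with per-decoy detail."""
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("PDB\tNRes\tNStructures\tSpecificity\n")
            for t in report["targets"]:
                fh.write(f"{t['PDB']}\t{t['NRes']}\t{t['NStructures']}\t"
                         f"{t['Specificity']:.4g}\n")
            fh.write(f"# mean_specificity\t{report['mean_specificity']:.4g}\n")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2)
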