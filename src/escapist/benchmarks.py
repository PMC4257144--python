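"""Published benchmark tables and their reconstruction through the ranking machinery.

The package ships the published per-target results of the reference C-beta scoring on
the standard decoy databases: the misfold set's correct/incorrect PDscore pairs, and the
per-target specificities on the 4state_reduced and hg_structal multi-decoy sets.  Feeding
the misfold score columns through :func:`escapist.scoring.rank_decoys` reproduces the
published binary specificity column; averaging the multi-decoy tables reproduces the
published set-level means.  Reproducing the scores themselves requires the decoy
structures and the external electrostatics toolchain (see docs/methods.md).
"""

from __future__ import annotations

import importlib.resources

from escapist.scoring import DecoyEvaluation, PDScoreResult, rank_decoys

__all__ = [
    "published_misfold_scores",
    "published_specificities",
    "reconstruct_misfold_evaluations",
    "mean_specificity",
]


def _read_rows(name: str) -> list[list[str]]:
    resource = importlib.resources.files("escapist.data") / name
    rows = []
    for line in resource.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    header, *body = rows
    return [dict(zip(header, r)) for r in body]


def published_misfold_scores() -> list[dict]:
    """Rows of the published misfold benchmark: PDB, NRES, CORRECT, INCORRECT."""
    rows = _read_rows("published_misfold_scores.tsv")
    return [{"PDB": r["PDB"], "NRES": int(r["NRES"]),
             "CORRECT": float(r["CORRECT"]), "INCORRECT": float(r["INCORRECT"])}
            for r in rows]


def published_specificities(set_name: str) -> list[dict]:
    """Published per-target specificities; ``set_name`` is '4state' or 'hg_structal'."""
    files = {"4state": "published_4state_specificities.tsv",
             "hg_structal": "published_hg_structal_specificities.tsv"}
    rows = _read_rows(files[set_name])
    return [{"PDB": r["PDB"], "NRES": int(r["NRES"]),
             "NSTRUCTURES": int(r["NSTRUCTURES"]),
             "SPECIFICITY": float(r["SPECIFICITY"])} for r in rows]


def reconstruct_misfold_evaluations() -> list[DecoyEvaluation]:
    """Rank each misfold target's incorrect structure against its correct one."""
    out = []
    for row in published_misfold_scores():
        native = PDScoreResult(pdscore=row["CORRECT"], numberCompared=row["NRES"] - 1)
        decoy = PDScoreResult(pdscore=row["INCORRECT"], numberCompared=row["NRES"] - 1)
        out.append(rank_decoys(native, {"incorrect": decoy}, targetId=row["PDB"]))
    return out


def mean_specificity(values) -> float:
    values = list(values)
    return sum(values) / len(values)
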