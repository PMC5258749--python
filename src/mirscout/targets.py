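"""miRNA target enrichment from a psRNATarget-dialect prediction table.

psRNATarget scores each miRNA-target pair with two quantities: UPE (target
site accessibility, a binding-energy surrogate; lower is better) and
Expectation (a randomness-of-match statistic similar to an E-value; lower is
more significant).  The most significant annotated target of each miRNA is
the one minimizing UPE + Expectation, raw and unweighted.  Targets without a
known functional annotation (uncharacterized/hypothetical/predicted/unknown
patterns) are excluded; a sum tie goes to the target whose annotation string
is most abundant across the whole annotated table, then to the
lexicographically smallest target id.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TargetRow",
    "EnrichedTarget",
    "DEFAULT_EXCLUSION_PATTERNS",
    "parse_psrnatarget",
    "write_psrnatarget",
    "enrich",
]

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSION_PATTERNS = ("uncharacterized", "hypothetical", "predicted protein", "unknown")

_MANDATORY = ("miRNA_Acc.", "Target_Acc.", "Expectation", "UPE")
_ALIASES = {  # header spellings seen in the wild
    "miRNA_Acc.": ("miRNA_Acc.", "miRNA_Acc", "miRNA"),
    "Target_Acc.": ("Target_Acc.", "Target_Acc", "Target"),
    "Expectation": ("Expectation",),
    "UPE": ("UPE",),
    "Inhibition": ("Inhibition", "Target_Desc."),
    "Multiplicity": ("Multiplicity",),
}


@dataclass(frozen=True)
class TargetRow:
    mirna_name: str
    target_id: str
    expectation: float
    upe: float
    inhibition_mode: str = "cleavage"  # cleavage | translation
    multiplicity: int = 1
    annotation: str = ""

    @property
    def score(self) -> float:
        return self.upe + self.expectation


@dataclass(frozen=True)
class EnrichedTarget:
    mirna_name: str
    target_id: str
    score: float
    annotation: str


def parse_psrnatarget(path: str | Path) -> list[TargetRow]:
    """Parse a tab-separated psRNATarget result table.

    Mandatory columns: miRNA_Acc., Target_Acc., Expectation, UPE (a missing
    one raises ``ValueError`` naming it); unknown extra columns are ignored;
    rows with malformed numeric fields are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols: dict[str, str] = {}
    for canonical, aliases in _ALIASES.items():
        for alias in aliases:
            if alias in df.columns:
                cols[canonical] = alias
                break
    missing = [c for c in _MANDATORY if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    rows: list[TargetRow] = []
    for i, rec in df.iterrows():
        try:
            expectation = float(rec[cols["Expectation"]])
            upe = float(rec[cols["UPE"]])
        except (TypeError, ValueError):
            logger.warning("%s: row %d has malformed numeric fields; skipped", path, i + 1)
            continue
        multiplicity = 1
        if "Multiplicity" in cols and pd.notna(rec[cols["Multiplicity"]]):
            try:
                multiplicity = int(float(rec[cols["Multiplicity"]]))
            except ValueError:
                pass
        inhibition = "cleavage"
        if "Inhibition" in cols and pd.notna(rec[cols["Inhibition"]]):
            inhibition = "translation" if "transl" in str(rec[cols["Inhibition"]]).lower() else "cleavage"
        rows.append(
            TargetRow(
                mirna_name=str(rec[cols["miRNA_Acc."]]),
                target_id=str(rec[cols["Target_Acc."]]),
                expectation=expectation,
                upe=upe,
                inhibition_mode=inhibition,
                multiplicity=max(1, multiplicity),
                annotation=str(rec["annotation"]) if "annotation" in df.columns and pd.notna(rec.get("annotation")) else "",
            )
        )
    return rows


def write_psrnatarget(rows: Iterable[TargetRow], path: str | Path) -> None:
    """Write rows back out in the same tab-separated dialect."""
    df = pd.DataFrame(
        {
            "miRNA_Acc.": [r.mirna_name for r in rows],
            "Target_Acc.": [r.target_id for r in rows],
            "Expectation": [r.expectation for r in rows],
            "UPE": [r.upe for r in rows],
            "Inhibition": [r.inhibition_mode.capitalize() for r in rows],
            "Multiplicity": [r.multiplicity for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _is_annotated(annotation: str, exclusion_patterns: Sequence[str]) -> bool:
    if not annotation or not annotation.strip():
        return False
    low = annotation.lower()
    return not any(pat in low for pat in exclusion_patterns)


def enrich(
    rows: Sequence[TargetRow],
    annotations: Mapping[str, str] | None = None,
    exclusion_patterns: Sequence[str] = DEFAULT_EXCLUSION_PATTERNS,
) -> dict[str, EnrichedTarget | None]:
    """Most significant annotated target per miRNA.

    ``annotations`` maps target id to a functional annotation string and
    overrides per-row annotations when given.  Candidates are rows with a
    known functional annotation (non-empty, not matching an exclusion
    pattern, case-insensitive substring).  Winner: minimal UPE+Expectation;
    tie → most abundant annotation string across the whole annotated table;
    remaining tie → lexicographically smallest target id (logged).  miRNAs
    with no annotated target map to None.  Deterministic under row shuffling.
    """
    annotated: list[tuple[TargetRow, str]] = []
    mirnas: list[str] = []
    for r in rows:
        if r.mirna_name not in mirnas:
            mirnas.append(r.mirna_name)
        ann = annotations.get(r.target_id, r.annotation) if annotations else r.annotation
        if _is_annotated(ann, exclusion_patterns):
            annotated.append((r, ann))
    abundance = Counter(ann for _, ann in annotated)
    out: dict[str, EnrichedTarget | None] = {}
    for name in mirnas:
        cands = [(r, ann) for r, ann in annotated if r.mirna_name == name]
        if not cands:
            out[name] = None
            continue
        best_score = min(r.score for r, _ in cands)
        tied = [(r, ann) for r, ann in cands if r.score == best_score]
        if len(tied) > 1:
            best_abundance = max(abundance[ann] for _, ann in tied)
            tied = [(r, ann) for r, ann in tied if abundance[ann] == best_abundance]
            if len(tied) > 1:
                tied.sort(key=lambda ra: ra[0].target_id)
                logger.info(
                    "%s: enrichment tie resolved lexicographically to %s",
                    name,
                    tied[0][0].target_id,
                )
        winner, ann = tied[0]
        out[name] = EnrichedTarget(
            mirna_name=name, target_id=winner.target_id, score=winner.score, annotation=ann
        )
    return out
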