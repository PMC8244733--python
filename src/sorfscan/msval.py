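"""MS-based sPeptide verification: digestion, unique-peptide mapping, UPN.

An sORF is *verified* when at least one identified peptide is a fully
tryptic fragment of exactly one entry in the combined sORF + canonical
protein database (unique peptide number, UPN >= 1). Peptides matching two or
more database entries are evidence for none of them; a peptide shared with a
canonical protein cannot evidence an sPeptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as pymass
from pyteomics import parser as pyparser

from .models import SorfscanError

__all__ = [
    "ValidationRecord",
    "tryptic_digest",
    "map_peptides",
    "monoisotopic_mass",
    "validation_rate_by_class",
    "verified_vs_unverified_contrast",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Cleave after K or R except when the next residue is P.
TRYPSIN_RULE = r"[KR](?!P)"

DEFAULT_MISSED_CLEAVAGES = 2
DEFAULT_MIN_LEN = 7
DEFAULT_MAX_LEN = 50


@dataclass(frozen=True)
class ValidationRecord:
    """Per-ORF verification outcome."""

    orf_id: str
    upn: int
    verified: bool
    samples: tuple[str, ...] = ()


def _check_residues(protein: str) -> None:
    for i, ch in enumerate(protein):
        if ch not in STANDARD_AA:
            raise SorfscanError(f"invalid residue {ch!r} at position {i}")


def tryptic_digest(
    protein: str,
    missed_cleavages: int = 0,
    min_len: int | None = None,
    max_len: int | None = None,
) -> list[str]:
    """In-silico trypsin digest, in N->C order (duplicates retained).

    With ``missed_cleavages=0`` and no length filter the fragments
    concatenate back to the input.
    """
    if not protein:
        raise SorfscanError("empty protein")
    protein = protein.upper()
    _check_residues(protein)
    frags = sorted(
        set(pyparser.icleave(protein, TRYPSIN_RULE,
                             missed_cleavages=missed_cleavages, regex=True)),
        key=lambda t: (t[0], len(t[1])),
    )
    out = [pep for _, pep in frags]
    if min_len is not None:
        out = [p for p in out if len(p) >= min_len]
    if max_len is not None:
        out = [p for p in out if len(p) <= max_len]
    return out


def monoisotopic_mass(peptide: str) -> float:
    """Monoisotopic peptide mass in Daltons (residues + one water)."""
    if not peptide:
        raise SorfscanError("empty peptide")
    _check_residues(peptide.upper())
    return float(pymass.calculate_mass(sequence=peptide.upper()))


def map_peptides(
    hits: pd.DataFrame,
    sorf_proteins: Mapping[str, str],
    canonical_proteins: Mapping[str, str],
    missed_cleavages: int = DEFAULT_MISSED_CLEAVAGES,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    merge_il: bool = False,
) -> tuple[list[ValidationRecord], list[str]]:
    """UPN per sORF from an identified-peptide table.

    A hit counts toward an sORF's UPN iff it is a valid tryptic peptide of
    exactly one entry in the combined sORF + canonical database. Returns the
    per-sORF records and the list of unassigned (zero-match) peptides.
    ``merge_il`` treats isoleucine and leucine as indistinguishable.
    """
    if not sorf_proteins and not canonical_proteins:
        raise SorfscanError("empty protein databases")

    def norm(p: str) -> str:
        p = p.upper()
        return p.replace("I", "L") if merge_il else p

    peptide_to_entries: dict[str, set[str]] = {}
    for db in (sorf_proteins, canonical_proteins):
        for entry, protein in db.items():
            for pep in set(tryptic_digest(protein, missed_cleavages, min_len, max_len)):
                peptide_to_entries.setdefault(norm(pep), set()).add(entry)

    upn: dict[str, set[str]] = {orf: set() for orf in sorf_proteins}
    samples: dict[str, set[str]] = {orf: set() for orf in sorf_proteins}
    unassigned: list[str] = []
    seen_unassigned: set[str] = set()
    for pep, grp in hits.groupby("peptide"):
        entries = peptide_to_entries.get(norm(str(pep)), set())
        if not entries:
            if pep not in seen_unassigned:
                unassigned.append(str(pep))
                seen_unassigned.add(str(pep))
            continue
        if len(entries) != 1:
            continue  # shared peptide: evidence for none
        (entry,) = entries
        if entry in upn:
            upn[entry].add(norm(str(pep)))
            samples[entry].update(grp["sample"].astype(str))
    records = [
        ValidationRecord(
            orf_id=orf,
            upn=len(upn[orf]),
            verified=len(upn[orf]) >= 1,
            samples=tuple(sorted(samples[orf])),
        )
        for orf in sorf_proteins
    ]
    return records, unassigned


def validation_rate_by_class(
    records: Sequence[ValidationRecord], orf_classes: Mapping[str, str]
) -> pd.DataFrame:
    """n_total / n_verified / rate per ORF class, plus an overall row."""
    rows = []
    by_class: dict[str, list[ValidationRecord]] = {}
    for rec in records:
        by_class.setdefault(orf_classes[rec.orf_id], []).append(rec)
    for cls in sorted(by_class):
        recs = by_class[cls]
        n_ver = sum(r.verified for r in recs)
        rows.append((cls, len(recs), n_ver, n_ver / len(recs)))
    n_all = len(records)
    n_ver_all = sum(r.verified for r in records)
    rows.append(("overall", n_all, n_ver_all, n_ver_all / n_all if n_all else 0.0))
    return pd.DataFrame(rows, columns=["class", "n_total", "n_verified", "rate"])


def verified_vs_unverified_contrast(
    records: Sequence[ValidationRecord],
    abundances: Mapping[str, float],
    lengths: Mapping[str, int],
) -> dict:
    """Rank-sum contrasts of abundance and length, verified vs unverified."""
    from .downstream import rank_sum_test

    ver = [r.orf_id for r in records if r.verified]
    unver = [r.orf_id for r in records if not r.verified]
    if len(ver) < 2 or len(unver) < 2:
        raise SorfscanError("both verified and unverified groups need >= 2 ORFs")
    out = {}
    for name, source in (("abundance", abundances), ("length", lengths)):
        a = np.asarray([source[o] for o in ver], dtype=float)
        b = np.asarray([source[o] for o in unver], dtype=float)
        u, p = rank_sum_test(a, b, alternative="greater")
        out[name] = {
            "u": u,
            "p": p,
            "median_verified": float(np.median(a)),
            "median_unverified": float(np.median(b)),
            "direction": "verified_greater" if np.median(a) > np.median(b) else "not_greater",
        }
    return out
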