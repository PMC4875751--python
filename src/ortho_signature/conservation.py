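"""Per-column conservation profiles: frequencies, entropy, logo heights.

Information content per column follows the classic sequence-logo
definition: IC = log2(20) - H - e_n, where H is the Shannon entropy of the
observed residue frequencies (gaps and 'X' excluded from the denominator)
and e_n = (s-1)/(2*ln(2)*n) is the asymptotic small-sample correction with
s = 20 states.  Letter heights are f * IC, so they stack to the column IC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .seqio import AMINO_ACIDS, GAP, MasterAlignment

LOG2_20 = math.log2(20)
#: Columns with more than this fraction of gaps are flagged as low-support.
GAP_FLAG_FRACTION = 0.5


@dataclass
class ColumnProfile:
    position: int                      # 1-based master column
    counts: dict[str, int]             # residue -> count (no gaps, no X)
    n_total: int                       # rows in the group
    e_n_correction: bool = True
    freqs: dict[str, float] = field(init=False)
    n_eff: int = field(init=False)
    H: float = field(init=False)
    e_n: float = field(init=False)
    IC: float = field(init=False)
    letter_heights: dict[str, float] = field(init=False)
    gap_flagged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.n_eff = sum(self.counts.values())
        if self.n_eff > 0:
            self.freqs = {r: c / self.n_eff for r, c in self.counts.items() if c > 0}
            self.H = -sum(f * math.log2(f) for f in self.freqs.values())
            self.e_n = (19.0 / (2.0 * math.log(2) * self.n_eff)
                        if self.e_n_correction else 0.0)
            self.IC = max(0.0, LOG2_20 - self.H - self.e_n)
        else:
            self.freqs, self.H, self.e_n, self.IC = {}, 0.0, 0.0, 0.0
        self.letter_heights = {r: f * self.IC for r, f in self.freqs.items()}
        gap_frac = 1.0 - self.n_eff / self.n_total if self.n_total else 0.0
        self.gap_flagged = gap_frac > GAP_FLAG_FRACTION

    @property
    def consensus(self) -> tuple[str, float]:
        """Modal residue and its frequency; ('-', 1.0) for an all-gap column."""
        if self.n_eff == 0:
            return GAP, 1.0
        best = max(sorted(self.freqs), key=lambda r: self.freqs[r])
        return best, self.freqs[best]


def column_profiles(master: MasterAlignment, group: list[str] | None = None,
                    e_n_correction: bool = True) -> list[ColumnProfile]:
    """Logo profile of every column, optionally restricted to a row subset."""
    ids = group if group is not None else list(master.ids)
    if not ids:
        raise ValidationError("empty group")
    sub = master.subset(ids)
    out = []
    for pos in range(1, sub.length + 1):
        col = sub.column(pos)
        counts: dict[str, int] = {}
        for ch in col:
            if ch in AMINO_ACIDS:
                counts[ch] = counts.get(ch, 0) + 1
        out.append(ColumnProfile(position=pos, counts=counts, n_total=len(ids),
                                 e_n_correction=e_n_correction))
    return out


def profiles_to_table(profiles: list[ColumnProfile], group_label: str = "") -> pd.DataFrame:
    """Tidy per-position/per-residue logo table (the plotting-ready export)."""
    rows = []
    for p in profiles:
        for r in sorted(p.counts):
            rows.append({
                "position": p.position, "residue": r, "count": p.counts[r],
                "freq": p.freqs[r], "height_bits": p.letter_heights[r],
                "ic_bits": p.IC, "gap_flagged": p.gap_flagged, "group": group_label,
            })
    return pd.DataFrame(rows, columns=["position", "residue", "count", "freq",
                                       "height_bits", "ic_bits", "gap_flagged", "group"])


def position_report(profiles_by_group: dict[str, list[ColumnProfile]],
                    positions: list[int]) -> pd.DataFrame:
    """Consensus residue per group at selected columns, with an
    acetylation-oriented note: K is acetylatable; R/H replacing a K preserve
    charge but not acetylation potential."""
    rows = []
    for group, profiles in profiles_by_group.items():
        by_pos = {p.position: p for p in profiles}
        for pos in positions:
            if pos not in by_pos:
                raise ValidationError(f"position {pos} outside alignment")
            prof = by_pos[pos]
            cons, f = prof.consensus
            if cons == "K":
                note = "acetylatable (K)"
            elif cons in ("R", "H"):
                note = "charge-preserving K replacement (non-acetylatable)"
            elif cons == GAP:
                note = "all-gap column"
            else:
                note = ""
            rows.append({"group": group, "position": pos, "consensus": cons,
                         "consensus_freq": round(f, 4), "n_eff": prof.n_eff,
                         "note": note})
    return pd.DataFrame(rows, columns=["group", "position", "consensus",
                                       "consensus_freq", "n_eff", "note"])


def motif_conservation(profiles: list[ColumnProfile], start: int, end: int,
                       motif: str) -> tuple[float, pd.DataFrame]:
    """Fraction of motif positions whose group consensus matches the motif.

    ``start``/``end`` are 1-based inclusive columns and must span exactly
    len(motif) positions (e.g. GVND over 143-146, LVIKTR over 159-164).
    """
    if end - start + 1 != len(motif):
        raise ValidationError("start..end span does not match motif length")
    by_pos = {p.position: p for p in profiles}
    rows = []
    matched = 0
    for k, expected in enumerate(motif.upper()):
        pos = start + k
        if pos not in by_pos:
            raise ValidationError(f"position {pos} outside alignment")
        prof = by_pos[pos]
        if prof.n_eff == 0:
            raise ValidationError(f"position {pos}: no residues in group")
        cons, f = prof.consensus
        ok = cons == expected
        matched += ok
        rows.append({"position": pos, "expected": expected, "consensus": cons,
                     "consensus_freq": round(f, 4), "match": ok})
    detail = pd.DataFrame(rows)
    return matched / len(motif), detail


def merge_profiles(a: ColumnProfile, b: ColumnProfile) -> ColumnProfile:
    """Count-weighted merge of two disjoint groups' profiles at one column."""
    if a.position != b.position:
        raise ValidationError("profiles are for different columns")
    counts = dict(a.counts)
    for r, c in b.counts.items():
        counts[r] = counts.get(r, 0) + c
    return ColumnProfile(position=a.position, counts=counts,
                         n_total=a.n_total + b.n_total,
                         e_n_correction=a.e_n_correction)
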