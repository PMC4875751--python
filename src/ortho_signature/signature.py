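"""Group-diagnostic signature segments and the global/local role classifier.

Segment notation follows the field's convention: uppercase = conserved in
the focal group AND discriminative against the other group, lowercase =
conserved in the focal group but shared with the other group, '*' =
wildcard (not conserved in the focal group).  The built-in eight-position
Lrp role scheme (D14>A, N21>K, E36>D, R40>K, F60>V, F80>V, S128>A,
D/E136>T) is expressed in anchor-sequence residue coordinates so that it
survives alignment-column drift between aligners.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .align import (DEFAULT_SCHEME, ScoringScheme, anchor_position_to_column,
                    global_align, map_query_to_master)
from .conservation import ColumnProfile
from .errors import ValidationError
from .seqio import GAP, MasterAlignment, ProteinSequence


@dataclass(frozen=True)
class SignatureSegment:
    start: int   # 1-based master column, inclusive
    end: int
    pattern: str  # uppercase / lowercase / '*'
    focal_group: str = ""
    n_uppercase: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.pattern):
            raise ValidationError("segment span does not match pattern length")
        object.__setattr__(self, "n_uppercase",
                           sum(ch.isupper() for ch in self.pattern))

    def __str__(self) -> str:
        return f"{self.start}-{self.pattern}-{self.end}"


@dataclass
class SignatureScheme:
    name: str
    anchor_id: str
    positions: list[int]
    global_consensus: list[set[str]]
    local_consensus: list[set[str]]
    coordinate: str = "anchor"  # "anchor" residue numbers or "master" columns

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValidationError("scheme positions must be strictly increasing")
        if not (len(self.positions) == len(self.global_consensus) == len(self.local_consensus)):
            raise ValidationError("scheme consensus lists must match positions")
        for g, l in zip(self.global_consensus, self.local_consensus):
            if not g or not l:
                raise ValidationError("empty consensus set")
            if set(g) & set(l):
                raise ValidationError("global and local consensus sets overlap")
        if self.coordinate not in ("anchor", "master"):
            raise ValidationError(f"unknown coordinate mode {self.coordinate!r}")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def to_json(self, path: str | Path) -> None:
        obj = {"name": self.name, "anchor_id": self.anchor_id,
               "coordinate": self.coordinate, "positions": self.positions,
               "global_consensus": [sorted(s) for s in self.global_consensus],
               "local_consensus": [sorted(s) for s in self.local_consensus]}
        Path(path).write_text(json.dumps(obj, indent=2))

    @staticmethod
    def from_json(path: str | Path) -> "SignatureScheme":
        obj = json.loads(Path(path).read_text())
        return SignatureScheme(
            name=obj["name"], anchor_id=obj["anchor_id"],
            coordinate=obj.get("coordinate", "anchor"),
            positions=list(obj["positions"]),
            global_consensus=[set(s) for s in obj["global_consensus"]],
            local_consensus=[set(s) for s in obj["local_consensus"]])


def load_lrp8_scheme() -> SignatureScheme:
    """The built-in 8-position Lrp global/local role scheme."""
    ref = importlib.resources.files("ortho_signature.data") / "lrp8_scheme.json"
    with importlib.resources.as_file(ref) as p:
        return SignatureScheme.from_json(p)


@dataclass(frozen=True)
class RolePrediction:
    query_id: str
    matches_global: int
    matches_local: int
    n_positions: int
    identity_to_anchor: float
    terminal_score: dict
    call: str            # "global" | "local" | "ambiguous"
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Segment extraction

def _classify_column(prof_focal: ColumnProfile, prof_other: ColumnProfile,
                     theta_cons: float, theta_disc: float) -> str:
    if prof_focal.n_eff == 0:
        return "*"
    res, f = prof_focal.consensus
    if res == GAP or f < theta_cons:
        return "*"
    f_other = prof_other.freqs.get(res, 0.0) if prof_other.n_eff > 0 else 0.0
    return res.upper() if f_other <= theta_disc else res.lower()


def extract_segments(profiles_A: list[ColumnProfile], profiles_B: list[ColumnProfile],
                     theta_cons: float = 0.9, theta_disc: float = 0.2,
                     min_len: int = 6, focal_group: str = "A") -> list[SignatureSegment]:
    """Signature segments of the focal group A against group B.

    Columns are classified uppercase/lowercase/'*' by the conservation and
    discrimination thresholds; segments are maximal stretches with no two
    consecutive wildcards, trimmed to start and end on conserved columns,
    and emitted when they contain >= min_len conserved positions.  Ordering
    is by the number of uppercase (group-specific) positions, descending,
    so the first segment is the most family-specific one.
    """
    for th in (theta_cons, theta_disc):
        if not 0.0 <= th <= 1.0:
            raise ValidationError("thresholds must lie in [0, 1]")
    if len(profiles_A) != len(profiles_B):
        raise ValidationError("profile lists cover different column sets")
    chars = [_classify_column(a, b, theta_cons, theta_disc)
             for a, b in zip(profiles_A, profiles_B)]
    segments: list[SignatureSegment] = []
    i = 0
    n = len(chars)
    while i < n:
        if chars[i] == "*":
            i += 1
            continue
        j = i
        while j + 1 < n:
            if chars[j + 1] != "*":
                j += 1
            elif j + 2 < n and chars[j + 2] != "*":  # tolerate isolated wildcard
                j += 2
            else:
                break
        pattern = "".join(chars[i:j + 1])
        # a segment must contain at least one discriminative (uppercase)
        # position: identical groups yield none, however conserved they are
        if (sum(c != "*" for c in pattern) >= min_len
                and any(c.isupper() for c in pattern)):
            segments.append(SignatureSegment(
                start=profiles_A[i].position, end=profiles_A[j].position,
                pattern=pattern, focal_group=focal_group))
        i = j + 1
    segments.sort(key=lambda s: (-s.n_uppercase, s.start))
    return segments


# ---------------------------------------------------------------------------
# Pattern matching

def match_signature(segment: SignatureSegment | str,
                    target: ProteinSequence) -> tuple[int, int, int]:
    """Best sliding-window match of a signature pattern against a sequence.

    Returns (offset, n_exact, n_mismatch) with offset 0-based; uppercase and
    lowercase positions require identity (case-insensitively), '*' matches
    anything.  Ties go to the smallest offset.
    """
    pattern = segment.pattern if isinstance(segment, SignatureSegment) else segment
    seq = target.residues
    if len(pattern) > len(seq):
        raise ValidationError("pattern longer than target sequence")
    pat = pattern.upper()
    best = None
    for off in range(len(seq) - len(pat) + 1):
        n_exact = n_mis = 0
        for k, pc in enumerate(pat):
            if pc == "*":
                continue
            if seq[off + k] == pc:
                n_exact += 1
            else:
                n_mis += 1
        if best is None or n_exact > best[1]:
            best = (off, n_exact, n_mis)
    return best


# ---------------------------------------------------------------------------
# Role classification

def classify_role(query: ProteinSequence, scheme: SignatureScheme,
                  master: MasterAlignment,
                  scoring: ScoringScheme = DEFAULT_SCHEME,
                  supermajority: float = 0.75,
                  n_tail_span: int = 21, c_motif: str = "LVIKTR") -> RolePrediction:
    """Score a query against the role scheme via the anchor row.

    If the query is itself a row of the master alignment its residues are
    read directly off that row (the scheme positions are scored on the mass
    alignment, exactly as one reads them off an underlined figure).  An
    external query is first projected into master coordinates through a
    pairwise alignment with the anchor row.  At each scheme position the
    residue is checked for membership in the global vs. local consensus
    sets; the call requires a 0.75 supermajority, and conflicting or
    gap-dominated evidence yields "ambiguous".  Terminal evidence
    (conserved N-tail coverage and the C-terminal multimerization-response
    block) is reported alongside.
    """
    if query.id in master.ids and master.degapped(query.id) == query.residues:
        row = master.row(query.id)
        mapping = {col: row[col - 1] for col in range(1, master.length + 1)}
    else:
        mapping = map_query_to_master(query, master, scheme.anchor_id, scoring)
    if scheme.coordinate == "anchor":
        columns = [anchor_position_to_column(master, scheme.anchor_id, p)
                   for p in scheme.positions]
    else:
        columns = list(scheme.positions)
    for col in columns:
        if not 1 <= col <= master.length:
            raise ValidationError(f"scheme column {col} outside alignment")
    matches_global = matches_local = n_gap = 0
    for col, gset, lset in zip(columns, scheme.global_consensus, scheme.local_consensus):
        res = mapping.get(col, GAP)
        if res == GAP:
            n_gap += 1
        elif res in gset:
            matches_global += 1
        elif res in lset:
            matches_local += 1
    n = scheme.n_positions
    low_conf = n_gap > n / 2
    need = math.ceil(supermajority * n)
    if low_conf:
        call = "ambiguous"
    elif matches_global >= need:
        call = "global"
    elif matches_local >= need:
        call = "local"
    else:
        call = "ambiguous"
    tail_cols = [c for c in range(1, min(n_tail_span, master.length) + 1)]
    n_tail_cov = sum(mapping.get(c, GAP) != GAP for c in tail_cols) / max(len(tail_cols), 1)
    _, n_exact, _ = match_signature(c_motif, query) if len(query) >= len(c_motif) \
        else (0, 0, len(c_motif))
    terminal = {"n_tail_coverage": n_tail_cov,
                "n_tail_present": n_tail_cov >= 0.5,
                "c_motif_identity": n_exact / len(c_motif),
                "c_motif_present": n_exact >= len(c_motif) - 1}
    anchor_seq = ProteinSequence(id=scheme.anchor_id,
                                 residues=master.degapped(scheme.anchor_id))
    ident = global_align(query, anchor_seq, scoring).identity_pct
    return RolePrediction(query_id=query.id, matches_global=matches_global,
                          matches_local=matches_local, n_positions=n,
                          identity_to_anchor=round(ident, 1),
                          terminal_score=terminal, call=call,
                          low_confidence=low_conf)
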