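"""Occurrence Frequency of Homologous-group in a Topology (OFHT).

A hierarchical domain-classification table (H-groups containing F-groups
containing domains, mirroring the ECOD homology/family levels) is scored per
topology ``T`` as::

    OFHT(T) = sum_i OR(T, i)
    OR(T, i) = (1 / N_family(i)) * sum_j N_domain(T, i, j) / N_domain(i, j)

i.e. the occupation ratio of ``T`` in H-group ``i`` is the mean, over its
F-groups, of the fraction of each F-group's domains carrying ``T``.  Domains
without a pure parallel sheet stay in the denominators but contribute to no
topology.  A topology with OFHT >= 3 is a *superfold* (observed across at
least three diverse homology groups); 0 < OFHT < 3 is a *normal fold*; 0 is
unobserved.

Topologies of individual domains are derived from abstract per-sheet records
(strand order, orientations, pairings, loop lengths) under four criteria:
(i) all sheet-adjacent strand pairs parallel, (ii) open sheet (no barrel),
(iii) no other sheet among the domain's strands, (iv) every inter-strand
loop shorter than 100 residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import CriterionRejection, DataError, SchemaError
from .topology import (
    SheetTopology,
    canonicalize,
    classify_topology,
    parse_topology,
    reverse_topology,
)

__all__ = [
    "Strand",
    "Pairing",
    "DomainSheetRecord",
    "EcodLikeTable",
    "OfhtTable",
    "MAX_LOOP_LENGTH",
    "derive_topology",
    "compute_or",
    "compute_ofht",
    "categorize_folds",
    "reverse_pair_report",
]

#: Criterion (iv): inter-strand loops must be shorter than this many residues.
MAX_LOOP_LENGTH = 100

SUPERFOLD_THRESHOLD = 3.0


@dataclass(frozen=True)
class Strand:
    index: int  # sequential order along the chain, 1-based
    position: int  # sheet position, 1-based left-to-right
    orientation: str = "up"


@dataclass(frozen=True)
class Pairing:
    a: int
    b: int
    relative: str  # "parallel" | "antiparallel"


@dataclass(frozen=True)
class DomainSheetRecord:
    """Abstract description of one domain's candidate pure parallel sheet."""

    domain_id: str
    strands: tuple[Strand, ...]
    pairings: tuple[Pairing, ...]
    barrel: bool = False
    sheet_count: int = 1
    loops: tuple[int, ...] = ()  # residues between consecutive strands

    def __post_init__(self):
        idx = {s.index for s in self.strands}
        for p in self.pairings:
            if p.a not in idx or p.b not in idx:
                raise SchemaError(
                    f"{self.domain_id}: pairing ({p.a},{p.b}) references unknown strand"
                )
        positions = sorted(s.position for s in self.strands)
        if positions != list(range(1, len(self.strands) + 1)):
            raise SchemaError(
                f"{self.domain_id}: sheet positions must form a contiguous 1..n range"
            )

    @classmethod
    def from_json(cls, text: str) -> "DomainSheetRecord":
        d = json.loads(text)
        return cls(
            domain_id=d["domain_id"],
            strands=tuple(
                Strand(s["index"], s["position"], s.get("orientation", "up"))
                for s in d["strands"]
            ),
            pairings=tuple(
                Pairing(p["a"], p["b"], p["relative"]) for p in d.get("pairings", ())
            ),
            barrel=bool(d.get("barrel", False)),
            sheet_count=int(d.get("sheet_count", 1)),
            loops=tuple(d.get("loops", ())),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "domain_id": self.domain_id,
                "strands": [
                    {"index": s.index, "position": s.position, "orientation": s.orientation}
                    for s in self.strands
                ],
                "pairings": [
                    {"a": p.a, "b": p.b, "relative": p.relative} for p in self.pairings
                ],
                "barrel": self.barrel,
                "sheet_count": self.sheet_count,
                "loops": list(self.loops),
            }
        )


def derive_topology(
    record: DomainSheetRecord, *, strict_single_sheet: bool = True
) -> SheetTopology:
    """Extract the canonical topology of a qualifying pure parallel sheet.

    Raises :class:`CriterionRejection` naming the first violated criterion.
    With ``strict_single_sheet=False`` criterion (iii) only requires that no
    strand is shared with another sheet (``sheet_count`` may exceed 1).
    """
    by_pos = {s.position: s for s in sorted(record.strands, key=lambda s: s.position)}
    n = len(record.strands)
    # criterion i: every sheet-adjacent pair must be declared parallel
    declared = {frozenset((p.a, p.b)): p.relative for p in record.pairings}
    for p in record.pairings:
        if p.relative == "antiparallel":
            raise CriterionRejection("i", f"{record.domain_id}: antiparallel pairing {p}")
    for pos in range(1, n):
        key = frozenset((by_pos[pos].index, by_pos[pos + 1].index))
        if declared.get(key) != "parallel":
            raise CriterionRejection(
                "i",
                f"{record.domain_id}: sheet-adjacent strands at positions "
                f"{pos},{pos + 1} lack a parallel pairing",
            )
    if any(s.orientation != "up" for s in record.strands):
        raise CriterionRejection(
            "i", f"{record.domain_id}: non-parallel strand orientation"
        )
    # criterion ii: open sheet
    if record.barrel:
        raise CriterionRejection("ii", f"{record.domain_id}: barrel sheet")
    # criterion iii: no other beta-sheets among the strands
    if strict_single_sheet and record.sheet_count != 1:
        raise CriterionRejection(
            "iii", f"{record.domain_id}: {record.sheet_count} sheets in domain"
        )
    # criterion iv: short inter-strand loops
    for k, loop in enumerate(record.loops, start=1):
        if loop >= MAX_LOOP_LENGTH:
            raise CriterionRejection(
                "iv",
                f"{record.domain_id}: loop {k} has {loop} residues "
                f"(must be < {MAX_LOOP_LENGTH})",
            )
    occupants = tuple(by_pos[pos].index for pos in range(1, n + 1))
    return canonicalize(SheetTopology(occupants))


# ---------------------------------------------------------------------------
# classification table


class EcodLikeTable:
    """(domain, H-group, F-group, topology) records.

    ``topology`` is a canonical arrow-dialect label or missing (NA) for
    domains without a qualifying pure parallel sheet.  Labels are
    canonicalised on ingest so flip-equivalent spellings aggregate.
    """

    COLUMNS = ["domain_id", "h_group", "f_group", "topology"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"table missing columns {sorted(missing)}")
        df = df[self.COLUMNS].copy()
        if df["domain_id"].duplicated().any():
            raise SchemaError("duplicate domain_id in table")
        fh = df.groupby("f_group")["h_group"].nunique()
        if (fh > 1).any():
            raise SchemaError(
                f"F-groups in multiple H-groups: {fh[fh > 1].index.tolist()}"
            )
        def _canon(label):
            if not isinstance(label, str) or label == "":
                return pd.NA
            return canonicalize(parse_topology(label)).format()
        df["topology"] = df["topology"].map(_canon)
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "EcodLikeTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                               na_values=[""]))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def n_h_groups(self) -> int:
        return self.df["h_group"].nunique()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class OfhtTable:
    """Per-topology OFHT values and the underlying per-H-group OR values."""

    ofht: pd.Series  # index: topology label, value: OFHT
    or_values: pd.DataFrame  # columns: topology, h_group, or_value
    n_h_groups: int

    def value(self, topology: SheetTopology | str) -> float:
        label = (
            canonicalize(parse_topology(topology)).format()
            if isinstance(topology, str)
            else canonicalize(topology).format()
        )
        return float(self.ofht.get(label, 0.0))


def compute_or(table: EcodLikeTable, topology: SheetTopology | str, h_group: str) -> float:
    """Occupation ratio OR(T, i): mean per-F-group fraction of domains with T."""
    label = (
        canonicalize(parse_topology(topology)).format()
        if isinstance(topology, str)
        else canonicalize(topology).format()
    )
    sub = table.df[table.df["h_group"] == h_group]
    if sub.empty:
        raise DataError(f"unknown H-group {h_group!r}")
    fracs = []
    for _, grp in sub.groupby("f_group"):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empty
            raise DataError("empty F-group")
        fracs.append((grp["topology"] == label).sum() / len(grp))
    return float(sum(fracs) / len(fracs))


def compute_ofht(table: EcodLikeTable) -> OfhtTable:
    """OFHT(T) for every topology observed in the table."""
    df = table.df
    rows = []
    for h, hgrp in df.groupby("h_group"):
        n_fam = hgrp["f_group"].nunique()
        frac = (
            hgrp.dropna(subset=["topology"])
            .groupby(["f_group", "topology"])
            .size()
            .div(hgrp.groupby("f_group").size(), level="f_group")
        )
        if len(frac):
            or_t = frac.groupby("topology").sum() / n_fam
            for topo, v in or_t.items():
                rows.append({"topology": topo, "h_group": h, "or_value": float(v)})
    or_df = pd.DataFrame(rows, columns=["topology", "h_group", "or_value"])
    ofht = (
        or_df.groupby("topology")["or_value"].sum().sort_values(ascending=False)
        if len(or_df)
        else pd.Series(dtype=float, name="or_value")
    )
    return OfhtTable(ofht=ofht, or_values=or_df, n_h_groups=table.n_h_groups)


def categorize_folds(
    ofht: OfhtTable, universe: Sequence[SheetTopology]
) -> pd.DataFrame:
    """Superfold / normal / unobserved category per universe topology.

    Observed topologies outside the universe (e.g. not clash-free) are kept
    in a separate ``outside_universe`` category rather than dropped.
    """
    labels = {canonicalize(t).format() for t in universe}
    rows = []
    for label in sorted(labels):
        v = float(ofht.ofht.get(label, 0.0))
        cat = (
            "superfold"
            if v >= SUPERFOLD_THRESHOLD
            else ("normal" if v > 0 else "unobserved")
        )
        rows.append({"topology": label, "ofht": v, "category": cat})
    for label, v in ofht.ofht.items():
        if label not in labels:
            rows.append(
                {"topology": label, "ofht": float(v), "category": "outside_universe"}
            )
    return pd.DataFrame(rows, columns=["topology", "ofht", "category"])


def reverse_pair_report(
    ofht: OfhtTable, universe: Sequence[SheetTopology]
) -> pd.DataFrame:
    """OFHT comparison across reverse-asymmetric frustration pairs.

    One row per unordered pair {T, reverse(T)} in the universe where exactly
    one member has N_FabP = 0; the frustration-free member comes first and
    ``free_dominates`` flags OFHT(free) >= OFHT(frustrated) (ties count).
    """
    cls = {t: classify_topology(t) for t in (canonicalize(u) for u in universe)}
    rows = []
    seen = set()
    for t, c in cls.items():
        r = c.reverse
        if r == t or frozenset((t, r)) in seen or r not in cls:
            continue
        seen.add(frozenset((t, r)))
        rc = cls[r]
        if (c.n_fabp == 0) == (rc.n_fabp == 0):
            continue
        free, frus = (c, rc) if c.n_fabp == 0 else (rc, c)
        v_free = ofht.value(free.topology)
        v_frus = ofht.value(frus.topology)
        rows.append(
            {
                "free_topology": free.topology.format(),
                "frustrated_topology": frus.topology.format(),
                "ofht_free": v_free,
                "ofht_frustrated": v_frus,
                "free_dominates": v_free >= v_frus,
            }
        )
    rows.sort(key=lambda r: -r["ofht_free"])
    return pd.DataFrame(
        rows,
        columns=[
            "free_topology", "frustrated_topology", "ofht_free",
            "ofht_frustrated", "free_dominates",
        ],
    )
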