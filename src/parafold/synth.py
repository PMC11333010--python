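"""Seeded synthetic inputs with the statistical structure the analysis expects.

The table generator emulates an ECOD-like hierarchy: H-groups containing
F-groups containing domains, a heavy-tailed topology-frequency distribution
(a few dominant folds, a long tail of rare ones), strong within-family label
correlation (families are evolutionarily related), a configurable fraction
of domains lacking a pure parallel sheet, and a configurable down-weighting
of frustrated topologies.  The generator targets the qualitative shape of
real fold-usage distributions, not fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .lattice import (
    Conformation,
    MotifCounts,
    contact_map,
)
from .ofht import DomainSheetRecord, EcodLikeTable, Pairing, Strand
from .topology import SheetTopology, classify_topology, enumerate_topologies, is_clash_free

__all__ = [
    "SyntheticTableSpec",
    "SheetRecordSet",
    "LatticeFixture",
    "generate_ecod_like_table",
    "generate_sheet_records",
    "generate_lattice_fixtures",
]


def _default_universe() -> tuple[SheetTopology, ...]:
    return tuple(t for t in enumerate_topologies(3, 6) if is_clash_free(t))


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Parameters of the synthetic classification-table generator.

    ``skew`` controls the stick-breaking concentration of topology
    frequencies (larger = heavier head, i.e. fewer topologies hold more of
    the mass).  ``frustration_bias`` multiplies the weight of topologies
    with N_FabP > 0 or N_j > 1 (0 suppresses them entirely).
    ``unlabeled_fraction`` is the probability that a domain lacks a pure
    parallel sheet and carries no topology label.
    """

    n_h_groups: int = 30
    f_groups_per_h: tuple[int, int] = (1, 6)
    domains_per_f: tuple[int, int] = (1, 20)
    topology_universe: tuple[SheetTopology, ...] | None = None
    skew: float = 4.0
    unlabeled_fraction: float = 0.55
    frustration_bias: float = 0.08
    within_f_concentration: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.unlabeled_fraction <= 1.0:
            raise SchemaError("unlabeled_fraction must be in [0, 1]")
        if not 0.0 <= self.within_f_concentration <= 1.0:
            raise SchemaError("within_f_concentration must be in [0, 1]")
        if self.skew <= 0 or self.frustration_bias < 0:
            raise SchemaError("skew must be > 0 and frustration_bias >= 0")

    def universe(self) -> tuple[SheetTopology, ...]:
        u = (
            self.topology_universe
            if self.topology_universe is not None
            else _default_universe()
        )
        if not u:
            raise SchemaError("empty topology universe")
        return u


def _topology_weights(spec: SyntheticTableSpec, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed weights via stick-breaking, damped for frustrated folds."""
    universe = spec.universe()
    k = len(universe)
    # GEM stick-breaking with Beta(1, 1/skew): larger skew -> heavier head
    v = rng.beta(1.0, 1.0 / spec.skew, size=k)
    sticks = v * np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
    order = rng.permutation(k)
    w = np.empty(k)
    w[order] = sticks
    for i, t in enumerate(universe):
        c = classify_topology(t)
        if c.n_fabp > 0 or c.n_jumps > 1:
            w[i] *= spec.frustration_bias
    total = w.sum()
    if total <= 0:
        raise SchemaError("all topology weights vanished; relax frustration_bias")
    return w / total


def generate_ecod_like_table(spec: SyntheticTableSpec) -> EcodLikeTable:
    """A deterministic synthetic H-group/F-group/domain table.

    Each H-group draws a dominant topology from the skewed distribution;
    each of its F-groups inherits that topology with probability
    ``within_f_concentration`` (else redraws), and all of a family's
    domains share the family topology, except the unlabeled fraction.
    """
    rng = np.random.default_rng(spec.seed)
    universe = spec.universe()
    labels = [t.format() for t in universe]
    weights = _topology_weights(spec, rng)
    rows = []
    domain_no = 0
    for h in range(spec.n_h_groups):
        h_id = f"H{h + 1:04d}"
        dominant = int(rng.choice(len(universe), p=weights))
        n_f = int(rng.integers(spec.f_groups_per_h[0], spec.f_groups_per_h[1] + 1))
        for f in range(n_f):
            f_id = f"{h_id}.F{f + 1:02d}"
            if rng.random() < spec.within_f_concentration:
                topo = dominant
            else:
                topo = int(rng.choice(len(universe), p=weights))
            n_d = int(rng.integers(spec.domains_per_f[0], spec.domains_per_f[1] + 1))
            for _ in range(n_d):
                domain_no += 1
                unlabeled = rng.random() < spec.unlabeled_fraction
                rows.append(
                    {
                        "domain_id": f"D{domain_no:06d}",
                        "h_group": h_id,
                        "f_group": f_id,
                        "topology": pd.NA if unlabeled else labels[topo],
                    }
                )
    return EcodLikeTable(pd.DataFrame(rows, columns=EcodLikeTable.COLUMNS))


# ---------------------------------------------------------------------------
# sheet records


@dataclass
class SheetRecordSet:
    records: list[DomainSheetRecord]
    manifest: pd.DataFrame  # domain_id, planted_topology, violation


def _record_for_topology(
    domain_id: str, t: SheetTopology, rng: np.random.Generator
) -> DomainSheetRecord:
    occ = t.occupants
    n = len(occ)
    strands = tuple(
        Strand(index=s, position=pos + 1, orientation="up") for pos, s in enumerate(occ)
    )
    pairings = tuple(
        Pairing(occ[pos], occ[pos + 1], "parallel") for pos in range(n - 1)
    )
    loops = tuple(int(rng.integers(2, 30)) for _ in range(n - 1))
    return DomainSheetRecord(
        domain_id=domain_id,
        strands=strands,
        pairings=pairings,
        barrel=False,
        sheet_count=1,
        loops=loops,
    )


def generate_sheet_records(
    spec: SyntheticTableSpec,
    n_records: int = 40,
    violation_proportions: dict[str, float] | None = None,
) -> SheetRecordSet:
    """Records with planted topologies plus controlled criterion violations.

    ``violation_proportions`` maps criterion names ("antiparallel",
    "barrel", "multi_sheet", "long_loop") to the fraction of records given
    that defect; remaining records are clean and round-trip through
    topology derivation.
    """
    props = violation_proportions or {}
    if sum(props.values()) > 1.0 + 1e-12:
        raise SchemaError("violation proportions sum to more than 1")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    universe = spec.universe()
    weights = _topology_weights(spec, np.random.default_rng(spec.seed))
    kinds = list(props) + ["clean"]
    cuts = np.cumsum([props[k] for k in props])
    records, rows = [], []
    for i in range(n_records):
        t = universe[int(rng.choice(len(universe), p=weights))]
        u = rng.random()
        kind = kinds[int(np.searchsorted(cuts, u, side="right"))] if len(cuts) else "clean"
        rec = _record_for_topology(f"S{i + 1:05d}", t, rng)
        if kind == "antiparallel":
            flip = rng.integers(0, len(rec.pairings))
            pair = rec.pairings[flip]
            rec = replace(
                rec,
                pairings=rec.pairings[:flip]
                + (Pairing(pair.a, pair.b, "antiparallel"),)
                + rec.pairings[flip + 1:],
            )
        elif kind == "barrel":
            rec = replace(rec, barrel=True)
        elif kind == "multi_sheet":
            rec = replace(rec, sheet_count=2)
        elif kind == "long_loop":
            k = int(rng.integers(0, len(rec.loops)))
            loops = list(rec.loops)
            loops[k] = int(rng.integers(100, 200))
            rec = replace(rec, loops=tuple(loops))
        records.append(rec)
        rows.append(
            {
                "domain_id": rec.domain_id,
                "planted_topology": t.format(),
                "violation": None if kind == "clean" else kind,
            }
        )
    return SheetRecordSet(records, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# lattice fixtures


@dataclass(frozen=True)
class LatticeFixture:
    name: str
    conformation: Conformation
    expected: MotifCounts
    expected_n_c: int


def _hamiltonian_4x4() -> Conformation:
    """A boustrophedon path over the 4x4 block (maximally compact, N_c = 9)."""
    pts = []
    for row in range(4):
        cols = range(4) if row % 2 == 0 else range(3, -1, -1)
        pts.extend((col, row) for col in cols)
    return Conformation(tuple(pts))


def generate_lattice_fixtures(
    L: int = 10, seed: int = 0, n_sequences: int = 8
) -> tuple[list[LatticeFixture], list[str]]:
    """Hand-constructed conformations with independently known annotations,
    plus seeded random HP sequences of length ``L``.

    Expected values are stated, not computed, so regression tests compare
    the annotation code against an independent reference.
    """
    fixtures = [
        LatticeFixture(
            "straight",
            Conformation.from_turns("S" * (L - 2)),
            MotifCounts(0, 0),
            0,
        ),
        # U-shape: single non-covalent contact (1,4); its corner pair is two
        # consecutive turns, which matches no straight-then-turn template.
        LatticeFixture("u_shape", Conformation.from_turns("LL"), MotifCounts(0, 0), 1),
        # straight run, turn, straight run: exactly one penalty window
        # (penalty_A) and one interior FLS
        LatticeFixture(
            "fls_interior", Conformation.from_turns("SLS"), MotifCounts(1, 1), 0
        ),
        # FLS at the very C-terminus: no penalty, no frustrated occurrence
        LatticeFixture(
            "fls_terminal", Conformation.from_turns("SL"), MotifCounts(0, 0), 0
        ),
        # reverse FLS at the N-terminus (turn, then straight): never penalised
        LatticeFixture(
            "reverse_fls", Conformation.from_turns("LS"), MotifCounts(0, 0), 0
        ),
    ]
    if L == 16:
        # 24 grid edges - 15 covalent bonds = 9 contacts; the three interior
        # about-faces contribute turn windows S-L-L, S-R-R, S-L-L (three
        # penalties) and straight-then-turn pairs at turns (2,3), (6,7),
        # (10,11) (three interior FLS occurrences)
        fixtures.append(
            LatticeFixture("compact_4x4", _hamiltonian_4x4(), MotifCounts(3, 3), 9)
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    sequences = [
        "".join(rng.choice(["H", "P"], size=L).tolist()) for _ in range(n_sequences)
    ]
    return fixtures, sequences
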