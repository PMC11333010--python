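"""Pure parallel beta-sheet topologies: enumeration, geometry and frustration.

A topology of an open, pure parallel beta-sheet with ``n`` strands is the
left-to-right order in which the sequentially numbered strands appear across
the sheet.  Strand ``k`` and strand ``k+1`` are joined by a crossover
connection (a beta-alpha-beta unit); assuming every crossover is right-handed,
the connection's alpha-helix sits on the sheet face determined by the crossing
direction.  Two quantities classify a topology:

* ``N_j`` — the number of *jumps*, strand pairs adjacent in sequence but not
  adjacent in the sheet;
* ``N_FabP`` — the number of *frustrated alpha-beta-unit pairings*: two
  alpha-beta units whose strands pair in the sheet while their helices sit on
  opposite faces, which makes the local hydrogen-bond register rules
  unsatisfiable.

A topology with ``N_FabP == 0`` and ``N_j <= 1`` is *frustration-free*.
Topologies are identified with their left-right mirror image, giving ``n!/2``
classes per strand count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import pandas as pd

from .errors import ResourceLimitError, SchemaError, UnsupportedOrientationError

__all__ = [
    "SheetTopology",
    "ConnectionGeometry",
    "TopologyClassification",
    "TopologySummary",
    "parse_topology",
    "canonicalize",
    "enumerate_topologies",
    "connection_geometry",
    "is_clash_free",
    "count_jumps",
    "count_fabp",
    "reverse_topology",
    "beta_rco",
    "classify_topology",
    "summarize_topology_set",
]

#: Largest strand count accepted by :func:`enumerate_topologies` (n!/2 growth).
MAX_ENUMERATION_N = 9

UP = "↑"
DOWN = "↓"


@dataclass(frozen=True, order=True)
class SheetTopology:
    """Strand order of a pure parallel sheet, read left to right.

    ``occupants[i]`` is the (1-based) strand index sitting at sheet position
    ``i+1``.  All strands point "up" (pure parallel sheet).
    """

    occupants: tuple[int, ...]

    def __post_init__(self):
        n = len(self.occupants)
        if n < 2 or sorted(self.occupants) != list(range(1, n + 1)):
            raise SchemaError(
                f"occupants must be a permutation of 1..n with n >= 2, got {self.occupants}"
            )

    @property
    def n_strands(self) -> int:
        return len(self.occupants)

    @property
    def positions(self) -> tuple[int, ...]:
        """Inverse map: ``positions[k-1]`` is the sheet position of strand k."""
        p = [0] * self.n_strands
        for pos, s in enumerate(self.occupants, start=1):
            p[s - 1] = pos
        return tuple(p)

    def position_of(self, strand: int) -> int:
        return self.positions[strand - 1]

    def flipped(self) -> "SheetTopology":
        """The left-right mirror image (same physical topology)."""
        return SheetTopology(tuple(reversed(self.occupants)))

    def is_canonical(self) -> bool:
        return self.occupants <= tuple(reversed(self.occupants))

    def format(self, dialect: str = "arrow") -> str:
        if dialect == "arrow":
            return "".join(f"{s}{UP}" for s in self.occupants)
        if dialect == "ascii":
            return "-".join(str(s) for s in self.occupants)
        raise ValueError(f"unknown dialect {dialect!r}")

    def __str__(self) -> str:
        return self.format()


@dataclass(frozen=True)
class ConnectionGeometry:
    """Geometry of the crossover connection from strand k to strand k+1.

    With all crossovers right-handed, a rightward crossing (``delta > 0``)
    places the helix on the front face and a leftward one on the back face;
    any globally consistent convention yields the same clash and pairing
    results.
    """

    strand: int  # connection joins strand and strand+1
    span_lo: int
    span_hi: int
    face: str  # "front" or "back"
    delta: int  # p(k+1) - p(k), never 0
    long_distance: bool  # skips more than two intervening strands

    def __post_init__(self):
        assert self.delta != 0 and self.face in ("front", "back")


@dataclass(frozen=True)
class TopologyClassification:
    """All per-topology classifier outputs."""

    topology: SheetTopology
    n_jumps: int
    n_fabp: int
    clash_free: bool
    beta_rco: float
    n_term_edge: bool
    c_term_edge: bool
    reverse: SheetTopology
    has_long_distance: bool

    @property
    def frustration_free(self) -> bool:
        return self.n_fabp == 0 and self.n_jumps <= 1


def parse_topology(text: str) -> SheetTopology:
    """Parse ``"2↑1↑3↑"``, ``"2-1-3"`` or ``"213"`` into a topology.

    The occupant order is kept exactly as written; canonicalization is a
    separate step.  Down arrows are rejected: only pure parallel sheets are
    representable.
    """
    text = text.strip()
    if not text:
        raise SchemaError("empty topology string")
    if DOWN in text:
        raise UnsupportedOrientationError(
            f"{text!r} contains a down strand; only pure parallel sheets are supported"
        )
    if UP in text:
        parts = [p for p in text.split(UP) if p != ""]
    elif "-" in text:
        parts = text.split("-")
    else:
        parts = list(text)  # bare digit-per-strand dialect
    try:
        occ = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise SchemaError(f"cannot parse topology string {text!r}") from exc
    n = len(occ)
    if sorted(occ) != list(range(1, n + 1)):
        raise SchemaError(
            f"{text!r}: occupants must contain each strand index 1..{n} exactly once"
        )
    return SheetTopology(occ)


def canonicalize(t: SheetTopology) -> SheetTopology:
    """Lexicographically smaller of the occupant list and its left-right flip."""
    return SheetTopology(min(t.occupants, tuple(reversed(t.occupants))))


def enumerate_topologies(n_min: int, n_max: int) -> list[SheetTopology]:
    """All canonical topology classes for each strand count in [n_min, n_max].

    There are exactly ``n!/2`` classes per strand count (``n >= 2``).  Output
    is ordered by strand count, then lexicographically.
    """
    if not 2 <= n_min <= n_max:
        raise SchemaError(f"need 2 <= n_min <= n_max, got ({n_min}, {n_max})")
    if n_max > MAX_ENUMERATION_N:
        raise ResourceLimitError(
            f"n_max={n_max} exceeds the exhaustive-enumeration limit "
            f"MAX_ENUMERATION_N={MAX_ENUMERATION_N}"
        )
    out: list[SheetTopology] = []
    for n in range(n_min, n_max + 1):
        seen = set()
        for perm in itertools.permutations(range(1, n + 1)):
            c = min(perm, tuple(reversed(perm)))
            if c not in seen:
                seen.add(c)
        out.extend(SheetTopology(c) for c in sorted(seen))
    return out


def connection_geometry(t: SheetTopology) -> list[ConnectionGeometry]:
    """Spans, faces and long-distance flags of the n-1 crossover connections."""
    p = t.positions
    conns = []
    for k in range(1, t.n_strands):
        a, b = p[k - 1], p[k]
        delta = b - a
        conns.append(
            ConnectionGeometry(
                strand=k,
                span_lo=min(a, b),
                span_hi=max(a, b),
                face="front" if delta > 0 else "back",
                delta=delta,
                long_distance=abs(delta) >= 4,
            )
        )
    return conns


def is_clash_free(t: SheetTopology) -> bool:
    """True unless two same-face connections have properly nested spans.

    Every right-handed crossover descends from the C-terminal end of one
    strand to the N-terminal start of the next, so all same-face connection
    arcs run in the same horizontal direction.  Two such arcs cross exactly
    when one span strictly contains the other; interleaved spans give
    parallel, non-crossing arcs.  Shared span endpoints (consecutive
    connections) never clash.
    """
    conns = connection_geometry(t)
    for a, b in itertools.combinations(conns, 2):
        if a.face != b.face:
            continue
        if (a.span_lo < b.span_lo and b.span_hi < a.span_hi) or (
            b.span_lo < a.span_lo and a.span_hi < b.span_hi
        ):
            return False
    return True


def count_jumps(t: SheetTopology) -> int:
    """N_j: sequence-adjacent strand pairs not adjacent in the sheet."""
    return sum(1 for c in connection_geometry(t) if abs(c.delta) > 1)


def count_fabp(t: SheetTopology) -> int:
    """N_FabP: frustrated alpha-beta-unit pairings.

    The alpha-beta units of connections k and m are frustrated as a pair when
    their strands (k+1 and m+1) sit at adjacent sheet positions — forming a
    parallel hydrogen-bonded pair — while the two helices lie on opposite
    faces of the sheet.
    """
    p = t.positions
    conns = connection_geometry(t)
    n = t.n_strands
    cnt = 0
    for k, m in itertools.combinations(range(1, n), 2):
        if abs(p[k] - p[m]) == 1 and conns[k - 1].face != conns[m - 1].face:
            cnt += 1
    return cnt


def reverse_topology(t: SheetTopology) -> SheetTopology:
    """The topology obtained by reversing the N-to-C chain direction.

    Strand k of the reversed chain is strand n+1-k of the original; sheet
    positions are unchanged.  An involution on canonical forms.
    """
    n = t.n_strands
    p = t.positions
    occ = [0] * n
    for k in range(1, n + 1):
        occ[p[n - k] - 1] = k
    return canonicalize(SheetTopology(tuple(occ)))


def beta_rco(t: SheetTopology) -> float:
    """Sheet-topology relative contact order.

    Mean sequence separation of the hydrogen-bonded (sheet-adjacent) strand
    pairs, normalised by the strand count: with ``N_pair = n - 1`` adjacent
    position pairs, ``betaRCO = (1 / (n * N_pair)) * sum |dM|`` where ``dM``
    is the strand-index difference across each pair.  Lies in
    ``[1/n, (n-1)/n]``.
    """
    occ = t.occupants
    n = t.n_strands
    return sum(abs(occ[i] - occ[i + 1]) for i in range(n - 1)) / (n * (n - 1))


def classify_topology(t: SheetTopology) -> TopologyClassification:
    t = canonicalize(t)
    p = t.positions
    n = t.n_strands
    return TopologyClassification(
        topology=t,
        n_jumps=count_jumps(t),
        n_fabp=count_fabp(t),
        clash_free=is_clash_free(t),
        beta_rco=beta_rco(t),
        n_term_edge=p[0] in (1, n),
        c_term_edge=p[n - 1] in (1, n),
        reverse=reverse_topology(t),
        has_long_distance=any(c.long_distance for c in connection_geometry(t)),
    )


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


GRID_FABP_ROWS = 3  # rows 0, 1, 2+
GRID_NJ_COLS = 6  # columns 0..5


@dataclass
class TopologySummary:
    """Aggregate statistics over a set of classified topologies."""

    n_topologies: int
    grid: list[list[int]]  # [N_FabP row 0/1/2+][N_j column 0..5]
    grid_overflow: int  # topologies with N_j > 5 (outside the printed grid)
    n_term_edge_pct: float  # one-decimal, half-up
    c_term_edge_pct: float
    frustration_free: list[SheetTopology]
    reverse_asymmetric_pairs: list[tuple[SheetTopology, SheetTopology]]
    table: pd.DataFrame = field(repr=False)

    @property
    def n_reverse_asymmetric_pairs(self) -> int:
        return len(self.reverse_asymmetric_pairs)


def classification_table(classifications: Iterable[TopologyClassification]) -> pd.DataFrame:
    """Fixed-column-order summary table (one row per topology)."""
    rows = [
        {
            "topology": c.topology.format(),
            "n_strands": c.topology.n_strands,
            "clash_free": c.clash_free,
            "n_jumps": c.n_jumps,
            "n_fabp": c.n_fabp,
            "beta_rco": c.beta_rco,
            "n_term_edge": c.n_term_edge,
            "c_term_edge": c.c_term_edge,
            "reverse_topology": c.reverse.format(),
            "long_distance": c.has_long_distance,
        }
        for c in classifications
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "topology", "n_strands", "clash_free", "n_jumps", "n_fabp",
            "beta_rco", "n_term_edge", "c_term_edge", "reverse_topology",
            "long_distance",
        ],
    )


def summarize_topology_set(
    topologies: Sequence[SheetTopology],
    *,
    clash_free_only: bool = False,
    max_fabp: int | None = None,
    max_jumps: int | None = None,
) -> TopologySummary:
    """Grid counts, edge statistics and reverse-pair census over a filtered set.

    The reverse-asymmetric pair count is the number of unordered pairs
    ``{T, reverse(T)}`` with ``T != reverse(T)`` inside the filtered set where
    exactly one member has ``N_FabP == 0``.
    """
    cls = [classify_topology(t) for t in topologies]
    sel = [
        c
        for c in cls
        if (not clash_free_only or c.clash_free)
        and (max_fabp is None or c.n_fabp <= max_fabp)
        and (max_jumps is None or c.n_jumps <= max_jumps)
    ]
    grid = [[0] * GRID_NJ_COLS for _ in range(GRID_FABP_ROWS)]
    overflow = 0
    for c in sel:
        row = min(c.n_fabp, GRID_FABP_ROWS - 1)
        if c.n_jumps < GRID_NJ_COLS:
            grid[row][c.n_jumps] += 1
        else:
            overflow += 1
    n = len(sel)
    ne = sum(1 for c in sel if c.n_term_edge)
    ce = sum(1 for c in sel if c.c_term_edge)
    by_topo = {c.topology: c for c in sel}
    pairs = []
    seen = set()
    for c in sel:
        r = c.reverse
        if r == c.topology or frozenset((c.topology, r)) in seen:
            continue
        seen.add(frozenset((c.topology, r)))
        rc = by_topo.get(r)
        if rc is None:
            continue
        if (c.n_fabp == 0) != (rc.n_fabp == 0):
            free, frus = (c, rc) if c.n_fabp == 0 else (rc, c)
            pairs.append((free.topology, frus.topology))
    return TopologySummary(
        n_topologies=n,
        grid=grid,
        grid_overflow=overflow,
        n_term_edge_pct=_round1(100.0 * ne / n) if n else 0.0,
        c_term_edge_pct=_round1(100.0 * ce / n) if n else 0.0,
        frustration_free=sorted(
            (c.topology for c in sel if c.frustration_free),
            key=lambda t: (t.n_strands, t.occupants),
        ),
        reverse_asymmetric_pairs=sorted(
            pairs, key=lambda p: (p[0].n_strands, p[0].occupants)
        ),
        table=classification_table(sel),
    )
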