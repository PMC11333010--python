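"""2D lattice HP model with sequence-independent local-structure penalties.

The chain is a self-avoiding walk on the square lattice; residues are H
(hydrophobic) or P (polar).  The energy of sequence ``s`` in conformation
``G`` is::

    E(s, G) = -eps_hh * n_HH(s, G) + eps_penalty * n_penalty(G)

where ``n_HH`` counts non-covalent lattice contacts between two H residues
and ``n_penalty`` counts occurrences of three short *penalty motifs* —
local backbone shapes declared physically unfavourable irrespective of
sequence.  The three motifs are the one-residue C-terminal extensions of a
four-residue *frustrated local structure* (FLS): a straight step followed by
a turn.  The FLS itself carries no penalty, but every way of continuing it
C-terminally does, so an interior FLS is frustrated while one at the very
C-terminus — and the chain-reversed motif — is not.  This direction
asymmetry is the lattice analogue of the frustrated alpha-beta-unit pairing
of real parallel-sheet proteins.

Designability ``N_s`` of a structure is the number of HP sequences whose
unique ground state it is; sequences with a unique ground state are
*protein-like*.  The scan is exhaustive over all ``2^L`` sequences and all
conformations, with conformations grouped by (contact set, penalty count)
and exact integer energies so ground-state ties are detected exactly.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import lcm
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import _kernels
from .errors import ResourceLimitError, SchemaError, TemplateValidationError

__all__ = [
    "Conformation",
    "ConformationSet",
    "MotifTemplate",
    "MotifTemplateSet",
    "EnergyParams",
    "StructureAnnotations",
    "MotifCounts",
    "DesignabilityResult",
    "LatticeGridSummary",
    "default_templates",
    "enumerate_conformations",
    "contact_map",
    "count_motifs",
    "verify_fls_frustration",
    "energy",
    "annotate_conformations",
    "designability_scan",
    "reverse_conformation",
    "rco",
    "grid_summary",
    "write_conformation_archive",
    "read_conformation_archive",
]

#: Hard ceiling for exhaustive walk enumeration (contact bit-masks need <= 64
#: possible pairs, satisfied up to L = 18).
MAX_ENUMERATION_L = 18
#: Hard ceiling for the exhaustive 2^L sequence scan.
MAX_SCAN_L = 16

_STEPS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _canonical_points(points: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Translate/rotate/mirror so p0 = origin, first step +x, first off-axis +y."""
    x0, y0 = points[0]
    pts = [(x - x0, y - y0) for x, y in points]
    dx, dy = pts[1]
    for _ in range(4):
        if (dx, dy) == (1, 0):
            break
        pts = [(y, -x) for x, y in pts]
        dx, dy = pts[1]
    for _, y in pts:
        if y != 0:
            if y < 0:
                pts = [(x, -y) for x, y in pts]
            break
    return tuple(pts)


@dataclass(frozen=True)
class Conformation:
    """A self-avoiding chain on the square lattice, N-terminus first."""

    points: tuple[tuple[int, int], ...]

    def __post_init__(self):
        pts = self.points
        if len(pts) < 2:
            raise SchemaError("a conformation needs at least 2 residues")
        if len(set(pts)) != len(pts):
            raise SchemaError("conformation is not self-avoiding")
        for (xa, ya), (xb, yb) in itertools.pairwise(pts):
            if abs(xa - xb) + abs(ya - yb) != 1:
                raise SchemaError("consecutive residues must differ by one unit step")

    @classmethod
    def from_turns(cls, turns: str, first: tuple[int, int] = (1, 0)) -> "Conformation":
        """Build from a turn string over {S, L, R} (first step ``first``)."""
        left = {(1, 0): (0, 1), (0, 1): (-1, 0), (-1, 0): (0, -1), (0, -1): (1, 0)}
        right = {v: k for k, v in left.items()}
        pts = [(0, 0), first]
        d = first
        for t in turns:
            if t == "L":
                d = left[d]
            elif t == "R":
                d = right[d]
            elif t != "S":
                raise SchemaError(f"bad turn symbol {t!r}")
            pts.append((pts[-1][0] + d[0], pts[-1][1] + d[1]))
        return cls(tuple(pts))

    @property
    def length(self) -> int:
        return len(self.points)

    def canonical(self) -> "Conformation":
        return Conformation(_canonical_points(self.points))

    def symmetry_images(self) -> set[tuple[tuple[int, int], ...]]:
        """The up-to-8 point-group images, origin-normalised, deduplicated."""
        out = set()
        pts = self.points
        for refl in (False, True):
            q = [(x, -y) for x, y in pts] if refl else list(pts)
            for _ in range(4):
                q = [(y, -x) for x, y in q]
                x0, y0 = q[0]
                out.add(tuple((x - x0, y - y0) for x, y in q))
        return out


def reverse_conformation(c: Conformation) -> Conformation:
    """Reverse the chain direction and re-canonicalise; an involution."""
    return Conformation(tuple(reversed(c.points))).canonical()


def contact_map(c: Conformation) -> frozenset[tuple[int, int]]:
    """Non-covalent lattice-adjacent residue pairs (0-based, i < j).

    On the square lattice every contact has odd separation ``j - i >= 3``.
    """
    where = {p: i for i, p in enumerate(c.points)}
    pairs = set()
    for i, (x, y) in enumerate(c.points):
        for dx, dy in _STEPS:
            j = where.get((x + dx, y + dy))
            if j is not None and j > i + 1:
                pairs.add((i, j))
    return frozenset(pairs)


def rco(c: Conformation) -> float | None:
    """Relative contact order: mean contact separation over chain length.

    ``RCO = (1 / (L * N)) * sum |i - j|`` over the N contacts; ``None``
    when the conformation has no contacts.
    """
    pairs = contact_map(c)
    if not pairs:
        return None
    return sum(j - i for i, j in pairs) / (c.length * len(pairs))


# ---------------------------------------------------------------------------
# motif templates


@dataclass(frozen=True)
class MotifTemplate:
    """A short directed walk whose symmetry images are matched along chains."""

    id: str
    path: tuple[tuple[int, int], ...]
    images: tuple[tuple[tuple[int, int], ...], ...] = field(init=False, repr=False)

    def __post_init__(self):
        conf = Conformation(self.path)  # validates the path is a SAW
        object.__setattr__(self, "images", tuple(sorted(conf.symmetry_images())))

    @property
    def length(self) -> int:
        return len(self.path)


@dataclass(frozen=True)
class MotifTemplateSet:
    penalties: tuple[MotifTemplate, MotifTemplate, MotifTemplate]
    fls: MotifTemplate

    @property
    def penalty_length(self) -> int:
        (q,) = {t.length for t in self.penalties}
        return q


def default_templates() -> MotifTemplateSet:
    """The built-in penalty motifs and FLS.

    The FLS is the 4-residue walk "straight step, then turn"; the penalty
    motifs are its three one-residue C-terminal continuations (turn sequences
    S-L-S, S-L-L, S-L-R).  This is the unique minimal template set for which
    the FLS is frustrated, its reverse is not, and the exhaustive L = 16
    designability census reproduces the reference structure counts.
    """
    return MotifTemplateSet(
        penalties=(
            MotifTemplate("penalty_A", ((0, 0), (1, 0), (2, 0), (2, 1), (2, 2))),
            MotifTemplate("penalty_B", ((0, 0), (1, 0), (2, 0), (2, 1), (1, 1))),
            MotifTemplate("penalty_C", ((0, 0), (1, 0), (2, 0), (2, 1), (3, 1))),
        ),
        fls=MotifTemplate("FLS", ((0, 0), (1, 0), (2, 0), (2, 1))),
    )


def _count_template_group(
    points: Sequence[tuple[int, int]],
    templates: Iterable[MotifTemplate],
    *,
    skip_terminal_window: bool = False,
    overlapping: bool = True,
) -> int:
    """Count windows matching any image of any template (direction-aware).

    A window matching several images of one template is counted once.  With
    ``overlapping=False`` a greedy left-to-right scan skips the residues of
    each accepted match (sensitivity analysis only; the reference counting is
    overlapping).
    """
    images_by_len: dict[int, set] = {}
    for t in templates:
        images_by_len.setdefault(t.length, set()).update(t.images)
    L = len(points)
    total = 0
    for m, images in sorted(images_by_len.items()):
        last = L - m + (0 if skip_terminal_window else 1)
        w = 0
        while w < last:
            x0, y0 = points[w]
            win = tuple((points[w + t][0] - x0, points[w + t][1] - y0) for t in range(m))
            if win in images:
                total += 1
                w += (m - 1) if not overlapping else 1
            else:
                w += 1
    return total


@dataclass(frozen=True)
class MotifCounts:
    n_penalty: int
    n_fls: int


def count_motifs(
    c: Conformation,
    templates: MotifTemplateSet | None = None,
    *,
    overlapping: bool = True,
) -> MotifCounts:
    """Penalty-motif and FLS occurrence counts for one conformation.

    ``n_penalty`` counts every window matching a penalty motif (any symmetry
    image, chain direction respected).  ``n_fls`` counts FLS occurrences the
    same way but excludes a window ending at the C-terminal residue: an FLS
    there can never be completed into a penalised shape, so it is not
    frustrated and carries no energetic consequence.
    """
    templates = templates or default_templates()
    return MotifCounts(
        n_penalty=_count_template_group(
            c.points, templates.penalties, overlapping=overlapping
        ),
        n_fls=_count_template_group(
            c.points, (templates.fls,), skip_terminal_window=True, overlapping=overlapping
        ),
    )


# ---------------------------------------------------------------------------
# template validation


@dataclass
class FrustrationCheck:
    name: str
    passed: bool
    detail: str


@dataclass
class FrustrationReport:
    checks: list[FrustrationCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def raise_if_failed(self):
        for c in self.checks:
            if not c.passed:
                raise TemplateValidationError(f"{c.name}: {c.detail}")


def verify_fls_frustration(templates: MotifTemplateSet | None = None) -> FrustrationReport:
    """Check that the template set realises the intended frustration pattern.

    (a) every self-avoiding one-residue C-terminal extension of the FLS
    contains at least one penalty motif; (b) the FLS itself contains none
    (hence an FLS at the chain's C-terminus is penalty-free); (c) the
    reverse FLS is penalty-free and admits at least one extension by one
    residue on *both* ends that stays penalty-free.
    """
    templates = templates or default_templates()
    fls_pts = list(templates.fls.path)
    pens = templates.penalties
    checks: list[FrustrationCheck] = []

    def n_pen(points):
        return _count_template_group(points, pens)

    # (b) first: the FLS alone carries no penalty
    checks.append(
        FrustrationCheck(
            "fls_penalty_free",
            n_pen(fls_pts) == 0,
            f"FLS {fls_pts} contains {n_pen(fls_pts)} penalty motifs (want 0)",
        )
    )
    # (a) every C-terminal extension penalised
    tail = fls_pts[-1]
    n_ext = 0
    for dx, dy in _STEPS:
        p = (tail[0] + dx, tail[1] + dy)
        if p in fls_pts:
            continue
        n_ext += 1
        ext = fls_pts + [p]
        checks.append(
            FrustrationCheck(
                f"extension_{p}_penalised",
                n_pen(ext) >= 1,
                f"C-terminal extension {ext} contains no penalty motif",
            )
        )
    checks.append(
        FrustrationCheck(
            "fls_extendable",
            n_ext > 0,
            "FLS admits no self-avoiding C-terminal extension",
        )
    )
    # (c) reverse FLS penalty-free and two-ended extension penalty-free
    rev = list(reversed(fls_pts))
    checks.append(
        FrustrationCheck(
            "reverse_fls_penalty_free",
            n_pen(rev) == 0,
            "the reverse FLS itself contains a penalty motif",
        )
    )
    free_ext = None
    for dn in _STEPS:
        head = (rev[0][0] - dn[0], rev[0][1] - dn[1])
        if head in rev:
            continue
        for dc in _STEPS:
            tail2 = (rev[-1][0] + dc[0], rev[-1][1] + dc[1])
            if tail2 in rev or tail2 == head:
                continue
            full = [head] + rev + [tail2]
            if n_pen(full) == 0:
                free_ext = full
                break
        if free_ext:
            break
    checks.append(
        FrustrationCheck(
            "reverse_fls_extendable_penalty_free",
            free_ext is not None,
            "no two-ended extension of the reverse FLS is penalty-free"
            if free_ext is None
            else f"e.g. {free_ext}",
        )
    )
    return FrustrationReport(checks)


# ---------------------------------------------------------------------------
# energies


@dataclass(frozen=True)
class EnergyParams:
    """Energy parameters: H-H contact reward and per-motif penalty."""

    eps_hh: float = 1.0
    eps_penalty: float = 2.0

    def __post_init__(self):
        if self.eps_hh < 0 or self.eps_penalty < 0:
            raise SchemaError("energy parameters must be non-negative")

    def as_integers(self) -> tuple[int, int]:
        """Scaled integer (eps_hh, eps_penalty) for exact tie detection."""
        fa = Fraction(self.eps_hh).limit_denominator(10**6)
        fb = Fraction(self.eps_penalty).limit_denominator(10**6)
        scale = lcm(fa.denominator, fb.denominator)
        return int(fa * scale), int(fb * scale)


def energy(
    sequence: str,
    c: Conformation,
    params: EnergyParams | None = None,
    templates: MotifTemplateSet | None = None,
) -> float:
    """Eq.-style total energy of one sequence in one conformation."""
    params = params or EnergyParams()
    if len(sequence) != c.length:
        raise SchemaError(
            f"sequence length {len(sequence)} != conformation length {c.length}"
        )
    if set(sequence) - {"H", "P"}:
        raise SchemaError("sequence must be over the alphabet {H, P}")
    n_hh = sum(1 for i, j in contact_map(c) if sequence[i] == "H" and sequence[j] == "H")
    counts = count_motifs(c, templates)
    return -params.eps_hh * n_hh + params.eps_penalty * counts.n_penalty


# ---------------------------------------------------------------------------
# exhaustive enumeration and bulk annotation


def _capacity(L: int) -> int:
    # canonical walk counts grow like mu^L / 8 with mu ~= 2.64; generous pad
    return max(64, int(2.8 ** (L - 1) / 4) + 1000)


class ConformationSet:
    """All canonical self-avoiding walks of a given length, densely stored."""

    def __init__(self, points: np.ndarray):
        self.points = points  # (n, L, 2) int8
        self._index: dict[bytes, int] | None = None

    @classmethod
    def enumerate(cls, L: int) -> "ConformationSet":
        if not 2 <= L <= MAX_ENUMERATION_L:
            raise ResourceLimitError(
                f"chain length {L} outside exhaustive range [2, {MAX_ENUMERATION_L}]"
            )
        return cls(_kernels.enumerate_saws(L, _capacity(L)))

    @property
    def L(self) -> int:
        return self.points.shape[1]

    def __len__(self) -> int:
        return self.points.shape[0]

    def __getitem__(self, i: int) -> Conformation:
        return Conformation(tuple(map(tuple, self.points[i].tolist())))

    def __iter__(self) -> Iterator[Conformation]:
        for i in range(len(self)):
            yield self[i]

    def index_of(self, c: Conformation) -> int:
        """Index of a conformation (canonicalised first); KeyError if absent."""
        if self._index is None:
            n, L, _ = self.points.shape
            self._index = {
                self.points[i].tobytes(): i for i in range(n)
            }
        key = np.asarray(_canonical_points(c.points), dtype=np.int8).tobytes()
        return self._index[key]

    def reverse_indices(self) -> np.ndarray:
        """Vectorised map i -> index of the chain-reversed conformation."""
        pts = self.points[:, ::-1, :].astype(np.int64)
        pts = pts - pts[:, :1, :]
        d = pts[:, 1, :]
        x, y = pts[..., 0].copy(), pts[..., 1].copy()
        # rotate so first step is +x
        for _ in range(3):
            bad = ~((d[:, 0] == 1) & (d[:, 1] == 0))
            if not bad.any():
                break
            x[bad], y[bad] = y[bad], -x[bad]
            d = np.stack([x[:, 1], y[:, 1]], axis=1)
        # mirror so first off-axis step is +y
        nz = y != 0
        first = np.where(nz.any(axis=1), nz.argmax(axis=1), 0)
        flip = y[np.arange(len(y)), first] < 0
        y[flip] = -y[flip]
        canon = np.stack([x, y], axis=2).astype(np.int8)
        if self._index is None:
            self.index_of(self[0])  # build index
        assert self._index is not None
        out = np.empty(len(self), dtype=np.int64)
        for i in range(len(self)):
            out[i] = self._index[canon[i].tobytes()]
        return out


def enumerate_conformations(L: int) -> ConformationSet:
    """Every L-residue self-avoiding walk modulo the 8 lattice symmetries."""
    return ConformationSet.enumerate(L)


@dataclass
class StructureAnnotations:
    """Per-conformation contact and motif annotations for a ConformationSet."""

    conformations: ConformationSet
    contact_masks: np.ndarray  # uint64 bitmask over possible pairs
    n_c: np.ndarray
    n_penalty: np.ndarray
    n_fls: np.ndarray
    templates: MotifTemplateSet

    @property
    def L(self) -> int:
        return self.conformations.L

    def rco_values(self) -> np.ndarray:
        """Per-structure RCO; NaN where a structure has no contacts."""
        L = self.L
        pairs = [(i, j) for i in range(L) for j in range(i + 3, L, 2)]
        sep = np.array([j - i for i, j in pairs], dtype=np.float64)
        masks = self.contact_masks
        total = np.zeros(len(masks), dtype=np.float64)
        for k, s in enumerate(sep):
            total += s * ((masks >> np.uint64(k)) & np.uint64(1)).astype(np.float64)
        n = self.n_c.astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, total / (L * n), np.nan)


def _images_array(templates: Iterable[MotifTemplate]) -> np.ndarray:
    images = sorted({img for t in templates for img in t.images})
    return np.array(images, dtype=np.int8)


def annotate_conformations(
    confs: ConformationSet, templates: MotifTemplateSet | None = None
) -> StructureAnnotations:
    """Bulk contact masks, contact counts and motif counts (numba kernel)."""
    templates = templates or default_templates()
    pen_images = _images_array(templates.penalties)
    fls_images = _images_array((templates.fls,))
    masks, n_c, n_pen, n_fls = _kernels.annotate(
        confs.points, pen_images, templates.penalty_length, fls_images,
        templates.fls.length,
    )
    return StructureAnnotations(confs, masks, n_c, n_pen, n_fls, templates)


# ---------------------------------------------------------------------------
# designability


@dataclass
class DesignabilityResult:
    """Outcome of the exhaustive sequence-structure scan.

    ``n_s[i]`` is the designability of conformation ``i``;
    ``min_energy[s]`` / ``n_ground[s]`` give, for sequence integer ``s``
    (residue ``i`` is H iff bit ``i`` of ``s`` is set), the ground-state
    energy and the exact number of conformations attaining it.
    """

    annotations: StructureAnnotations
    params: EnergyParams
    n_s: np.ndarray
    min_energy: np.ndarray  # scaled integer units
    n_ground: np.ndarray
    energy_scale: int  # min_energy / energy_scale is in physical units

    @property
    def protein_like_count(self) -> int:
        return int(np.sum(self.n_ground == 1))

    @property
    def L(self) -> int:
        return self.annotations.L

    def sequence_string(self, s: int) -> str:
        return "".join("H" if (s >> i) & 1 else "P" for i in range(self.L))


def _sequence_pair_masks(L: int) -> np.ndarray:
    pairs = [(i, j) for i in range(L) for j in range(i + 3, L, 2)]
    seqs = np.arange(1 << L, dtype=np.uint64)
    spm = np.zeros(1 << L, dtype=np.uint64)
    for k, (i, j) in enumerate(pairs):
        both = ((seqs >> np.uint64(i)) & np.uint64(1)) & (
            (seqs >> np.uint64(j)) & np.uint64(1)
        )
        spm |= both << np.uint64(k)
    return spm


def designability_scan(
    L: int = 16,
    params: EnergyParams | None = None,
    templates: MotifTemplateSet | None = None,
    *,
    annotations: StructureAnnotations | None = None,
    validate_templates: bool = True,
) -> DesignabilityResult:
    """Exhaustive ground-state census over all 2^L sequences.

    Conformations are grouped into (contact set, n_penalty) classes with
    multiplicities; a class with multiplicity > 1 at the minimum disqualifies
    uniqueness, so protein-likeness is decided per conformation, not per
    class.  Energies are compared in exact scaled-integer arithmetic.
    """
    params = params or EnergyParams()
    if annotations is None:
        if not 2 <= L <= MAX_SCAN_L:
            raise ResourceLimitError(
                f"chain length {L} outside exhaustive scan range [2, {MAX_SCAN_L}]"
            )
        templates = templates or default_templates()
        if validate_templates:
            verify_fls_frustration(templates).raise_if_failed()
        annotations = annotate_conformations(enumerate_conformations(L), templates)
    else:
        L = annotations.L
        if L > MAX_SCAN_L:
            raise ResourceLimitError(f"chain length {L} too large for 2^L scan")
        if validate_templates:
            verify_fls_frustration(annotations.templates).raise_if_failed()

    a_int, b_int = params.as_integers()
    scale = round(a_int / params.eps_hh) if params.eps_hh else (
        round(b_int / params.eps_penalty) if params.eps_penalty else 1
    )

    keys = np.stack(
        [annotations.contact_masks, annotations.n_penalty.astype(np.uint64)], axis=1
    )
    uniq, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    class_masks = uniq[:, 0].astype(np.uint64)
    class_pen = uniq[:, 1].astype(np.int16)
    class_mult = counts.astype(np.int32)

    spm = _sequence_pair_masks(L)
    min_e, n_ground, class_ns = _kernels.scan_ground_states(
        class_masks, class_pen, class_mult, spm, a_int, b_int
    )
    n_s = np.zeros(len(annotations.conformations), dtype=np.int64)
    single = class_mult[inverse] == 1
    n_s[single] = class_ns[inverse[single]]
    return DesignabilityResult(
        annotations=annotations,
        params=params,
        n_s=n_s,
        min_energy=min_e,
        n_ground=n_ground,
        energy_scale=int(scale) if scale else 1,
    )


# ---------------------------------------------------------------------------
# grids and reports


@dataclass
class LatticeGridSummary:
    """Structure counts on the (N_FLS row, N_c column) grid, plus extras."""

    nc_columns: list[int]
    counts_all: np.ndarray  # (3, 6): N_FLS rows 0/1/2+, N_c columns
    counts_high: np.ndarray
    overflow_all: int  # structures whose N_c falls outside the columns
    overflow_high: int
    threshold: int
    designability_histogram: np.ndarray  # bincount over N_s
    reverse_pairs: "np.ndarray"  # (k, 4): i, rev_i, n_s[i], n_s[rev_i]


def grid_summary(
    result: DesignabilityResult, threshold: int = 100, n_columns: int = 6
) -> LatticeGridSummary:
    """Fig-style grid of all vs highly designable structures.

    Columns are the ``n_columns`` highest observed contact counts (4..9 for
    L = 16); rows bin N_FLS as 0, 1, 2+.  Also reports the designability
    histogram and the structure/reverse scatter restricted to pairs where
    one member is FLS-free and its reverse is not.
    """
    ann = result.annotations
    n_c = ann.n_c
    n_fls = ann.n_fls
    cols = sorted(np.unique(n_c).tolist())[-n_columns:]
    col_of = {v: k for k, v in enumerate(cols)}
    counts_all = np.zeros((3, len(cols)), dtype=np.int64)
    counts_high = np.zeros((3, len(cols)), dtype=np.int64)
    high = result.n_s >= threshold
    overflow_all = overflow_high = 0
    for i in range(len(n_c)):
        row = min(int(n_fls[i]), 2)
        k = col_of.get(int(n_c[i]))
        if k is None:
            overflow_all += 1
            overflow_high += int(high[i])
            continue
        counts_all[row, k] += 1
        counts_high[row, k] += int(high[i])
    rev = ann.conformations.reverse_indices()
    sel = (n_fls == 0) & (n_fls[rev] > 0)
    idx = np.nonzero(sel)[0]
    pairs = np.stack(
        [idx, rev[idx], result.n_s[idx], result.n_s[rev[idx]]], axis=1
    )
    return LatticeGridSummary(
        nc_columns=cols,
        counts_all=counts_all,
        counts_high=counts_high,
        overflow_all=overflow_all,
        overflow_high=overflow_high,
        threshold=threshold,
        designability_histogram=np.bincount(result.n_s),
        reverse_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# archive I/O


def write_conformation_archive(path, confs: ConformationSet) -> None:
    """One walk per line as comma-separated "x y" coordinate pairs (gzip)."""
    with gzip.open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# parafold conformations L={confs.L} "
                 f"canonical=first-step+x,first-turn+y\n")
        for i in range(len(confs)):
            fh.write(
                ",".join(f"{x} {y}" for x, y in confs.points[i].tolist()) + "\n"
            )


def read_conformation_archive(path) -> ConformationSet:
    rows = []
    L = None
    with gzip.open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            pts = [tuple(map(int, tok.split())) for tok in line.strip().split(",")]
            if L is None:
                L = len(pts)
            elif len(pts) != L:
                raise SchemaError("inconsistent walk lengths in archive")
            rows.append(pts)
    if not rows:
        raise SchemaError("empty conformation archive")
    return ConformationSet(np.array(rows, dtype=np.int8))
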