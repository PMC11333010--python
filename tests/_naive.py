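"""Independent brute-force oracles used to validate the package kernels.

Everything here is deliberately simple and separate from the package
implementation: plain-Python depth-first enumeration without symmetry
pruning, dictionary-based symmetry dedup, and a per-conformation (ungrouped)
numpy energy scan with float energies.
"""

import itertools

import numpy as np

STEPS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def naive_enumerate(L):
    """All self-avoiding walks of L residues, deduped by the cheapest possible
    normalisation: the lexicographic minimum over the 8 symmetry images."""
    classes = set()

    def images(pts):
        out = []
        for refl in (False, True):
            q = [(x, -y) for x, y in pts] if refl else list(pts)
            for _ in range(4):
                q = [(y, -x) for x, y in q]
                x0, y0 = q[0]
                out.append(tuple((x - x0, y - y0) for x, y in q))
        return out

    def walk(pts, seen):
        if len(pts) == L:
            classes.add(min(images(pts)))
            return
        x, y = pts[-1]
        for dx, dy in STEPS:
            p = (x + dx, y + dy)
            if p not in seen:
                walk(pts + [p], seen | {p})

    walk([(0, 0)], {(0, 0)})
    return classes


def naive_class(points):
    """The same normalisation, for mapping package output into oracle space."""
    out = []
    pts = [tuple(p) for p in points]
    for refl in (False, True):
        q = [(x, -y) for x, y in pts] if refl else list(pts)
        for _ in range(4):
            q = [(y, -x) for x, y in q]
            x0, y0 = q[0]
            out.append(tuple((x - x0, y - y0) for x, y in q))
    return min(out)


def naive_contacts(points):
    where = {tuple(p): i for i, p in enumerate(points)}
    pairs = set()
    for i, (x, y) in enumerate(points):
        for dx, dy in STEPS:
            j = where.get((x + dx, y + dy))
            if j is not None and j > i + 1:
                pairs.add((i, j))
    return sorted(pairs)


def naive_count_penalties(points, penalty_paths):
    """Window-by-window matching against explicitly enumerated images."""
    images = set()
    for path in penalty_paths:
        pts = [tuple(p) for p in path]
        for refl in (False, True):
            q = [(x, -y) for x, y in pts] if refl else list(pts)
            for _ in range(4):
                q = [(y, -x) for x, y in q]
                x0, y0 = q[0]
                images.add(tuple((x - x0, y - y0) for x, y in q))
    m = len(penalty_paths[0])
    cnt = 0
    for w in range(len(points) - m + 1):
        x0, y0 = points[w][0], points[w][1]
        win = tuple((points[w + t][0] - x0, points[w + t][1] - y0) for t in range(m))
        if win in images:
            cnt += 1
    return cnt


def naive_designability(conf_points, penalty_paths, eps_hh, eps_penalty):
    """Ungrouped, per-conformation float-energy ground-state census.

    Returns (protein_like_count, n_s array, min_energy array).
    """
    n_conf = len(conf_points)
    L = len(conf_points[0])
    n_seq = 1 << L
    seqs = np.arange(n_seq, dtype=np.int64)
    bits = np.stack([(seqs >> i) & 1 for i in range(L)], axis=0).astype(np.int8)
    energies = np.zeros((n_conf, n_seq), dtype=np.float64)
    for c, pts in enumerate(conf_points):
        pen = naive_count_penalties(pts, penalty_paths) if eps_penalty else 0
        n_hh = np.zeros(n_seq, dtype=np.int64)
        for i, j in naive_contacts(pts):
            n_hh += bits[i] * bits[j]
        energies[c] = -eps_hh * n_hh + eps_penalty * pen
    min_e = energies.min(axis=0)
    at_min = energies == min_e[None, :]
    counts = at_min.sum(axis=0)
    unique = counts == 1
    n_s = (at_min & unique[None, :]).sum(axis=1)
    return int(unique.sum()), n_s, min_e
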