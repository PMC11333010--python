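"""Numba kernels for the exhaustive lattice enumeration, annotation and scan.

These are internal: :mod:`parafold.lattice` wraps them with validated, typed
entry points.  All kernels are deterministic; the enumeration emits walks in
depth-first order over the step choices (+x, -x, +y, -y).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def enumerate_saws(L, cap):
    """Canonical self-avoiding walks of L residues on the square lattice.

    Canonical form quotients the 8 lattice symmetries: first point at the
    origin, first step +x, first off-axis step (if any) toward +y.  Returns
    an int8 array of shape (n_walks, L, 2); raises if more than ``cap`` walks
    are produced.
    """
    out = np.zeros((cap, L, 2), dtype=np.int8)
    if L == 2:
        out[0, 1, 0] = 1
        return out[:1]
    nout = 0
    xs = np.zeros(L, dtype=np.int64)
    ys = np.zeros(L, dtype=np.int64)
    off = L + 1
    board = np.zeros((2 * off + 1, 2 * off + 1), dtype=np.uint8)
    xs[1] = 1
    board[off, off] = 1
    board[off + 1, off] = 1
    dirx = (1, -1, 0, 0)
    diry = (0, 0, 1, -1)
    depth = 2
    choice = np.zeros(L + 1, dtype=np.int64)
    # deviated[d]: whether positions < d include any off-axis point
    deviated = np.zeros(L + 1, dtype=np.uint8)
    while depth >= 2:
        if depth == L:
            if nout >= cap:
                raise RuntimeError("enumeration capacity exceeded")
            for i in range(L):
                out[nout, i, 0] = xs[i]
                out[nout, i, 1] = ys[i]
            nout += 1
            depth -= 1
            board[xs[depth] + off, ys[depth] + off] = 0
            continue
        c = choice[depth]
        if c >= 4:
            choice[depth] = 0
            depth -= 1
            if depth >= 2:
                board[xs[depth] + off, ys[depth] + off] = 0
            continue
        choice[depth] = c + 1
        if diry[c] == -1 and not deviated[depth]:
            continue  # first off-axis step must be +y
        nx = xs[depth - 1] + dirx[c]
        ny = ys[depth - 1] + diry[c]
        if board[nx + off, ny + off]:
            continue
        xs[depth] = nx
        ys[depth] = ny
        board[nx + off, ny + off] = 1
        deviated[depth + 1] = deviated[depth] or (ny != 0)
        depth += 1
    return out[:nout]


@njit(cache=True)
def annotate(confs, pen_images, pen_len, fls_images, fls_len):
    """Contact masks, contact counts, penalty-motif and FLS counts.

    ``pen_images`` / ``fls_images`` are (n_images, length, 2) arrays of
    origin-normalised template images (all symmetry copies, deduplicated).
    Penalty motifs are counted over every window; FLS occurrences only over
    windows that do not end at the C-terminal residue, because a C-terminal
    FLS is not frustrated.  The contact mask sets one bit per possible
    non-covalent adjacent pair (i, j), j - i odd and >= 3, in row-major pair
    order; chain lengths up to 18 fit in 64 bits.
    """
    n, L, _ = confs.shape
    n_pen_img = pen_images.shape[0]
    n_fls_img = fls_images.shape[0]
    masks = np.zeros(n, dtype=np.uint64)
    n_c = np.zeros(n, dtype=np.int16)
    n_pen = np.zeros(n, dtype=np.int16)
    n_fls = np.zeros(n, dtype=np.int16)
    pidx = np.full((L, L), -1, dtype=np.int16)
    k = 0
    for i in range(L):
        for j in range(i + 3, L, 2):
            pidx[i, j] = k
            k += 1
    off = L + 2
    board = np.full((2 * off + 1, 2 * off + 1), -1, dtype=np.int16)
    for c in range(n):
        for i in range(L):
            board[confs[c, i, 0] + off, confs[c, i, 1] + off] = i
        m = np.uint64(0)
        nc = 0
        for i in range(L):
            x = confs[c, i, 0] + off
            y = confs[c, i, 1] + off
            for d in range(4):
                if d == 0:
                    j = board[x + 1, y]
                elif d == 1:
                    j = board[x - 1, y]
                elif d == 2:
                    j = board[x, y + 1]
                else:
                    j = board[x, y - 1]
                if j > i + 1:
                    nc += 1
                    m |= np.uint64(1) << np.uint64(pidx[i, j])
        masks[c] = m
        n_c[c] = nc
        cnt = 0
        for w in range(L - pen_len + 1):
            x0 = confs[c, w, 0]
            y0 = confs[c, w, 1]
            for im in range(n_pen_img):
                ok = True
                for t in range(pen_len):
                    if (
                        confs[c, w + t, 0] - x0 != pen_images[im, t, 0]
                        or confs[c, w + t, 1] - y0 != pen_images[im, t, 1]
                    ):
                        ok = False
                        break
                if ok:
                    cnt += 1
                    break
        n_pen[c] = cnt
        cnt = 0
        for w in range(L - fls_len):  # C-terminal window excluded
            x0 = confs[c, w, 0]
            y0 = confs[c, w, 1]
            for im in range(n_fls_img):
                ok = True
                for t in range(fls_len):
                    if (
                        confs[c, w + t, 0] - x0 != fls_images[im, t, 0]
                        or confs[c, w + t, 1] - y0 != fls_images[im, t, 1]
                    ):
                        ok = False
                        break
                if ok:
                    cnt += 1
                    break
        n_fls[c] = cnt
        for i in range(L):
            board[confs[c, i, 0] + off, confs[c, i, 1] + off] = -1
    return masks, n_c, n_pen, n_fls


@njit(cache=True, inline="always")
def _popcount64(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> np.uint64(2)) & np.uint64(0x3333333333333333)
    )
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(cache=True)
def scan_ground_states(class_masks, class_pen, class_mult, seq_pair_masks, a_int, b_int):
    """Exact integer ground-state scan over all sequences.

    Conformations are pre-grouped into (contact set, n_penalty) classes with
    multiplicities.  For each sequence the minimum energy
    ``E = -a_int * n_HH + b_int * n_penalty`` and the exact number of
    conformations attaining it are tracked; a sequence is protein-like iff
    that count is 1, and the unique minimiser's class (necessarily of
    multiplicity 1) accumulates its designability N_s.

    Returns (min_energy, n_ground, class_ns).
    """
    n_cls = class_masks.shape[0]
    n_seq = seq_pair_masks.shape[0]
    min_e = np.full(n_seq, np.int64(2) ** 60, dtype=np.int64)
    n_ground = np.zeros(n_seq, dtype=np.int64)
    for c in range(n_cls):
        pen = np.int64(b_int) * np.int64(class_pen[c])
        mc = class_masks[c]
        mult = np.int64(class_mult[c])
        for s in range(n_seq):
            e = pen - np.int64(a_int) * np.int64(_popcount64(seq_pair_masks[s] & mc))
            if e < min_e[s]:
                min_e[s] = e
                n_ground[s] = mult
            elif e == min_e[s]:
                n_ground[s] += mult
    class_ns = np.zeros(n_cls, dtype=np.int64)
    for c in range(n_cls):
        if class_mult[c] != 1:
            continue
        pen = np.int64(b_int) * np.int64(class_pen[c])
        mc = class_masks[c]
        for s in range(n_seq):
            if n_ground[s] == 1:
                e = pen - np.int64(a_int) * np.int64(_popcount64(seq_pair_masks[s] & mc))
                if e == min_e[s]:
                    class_ns[c] += 1
    return min_e, n_ground, class_ns
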