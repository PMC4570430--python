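"""Independent brute-force reference implementations used only by tests.

These re-derive the windowed mean-shift mode seeking and the divergence
scatter-point rule with literal per-pixel loops, sharing no code with the
production (vectorized) paths.
"""
import numpy as np


def mean_shift_modes_bruteforce(norm, valid, sp, sr, max_iter, eps):
    """Per-pixel mode seeking: y <- mean of window depths within sr of y."""
    h, w = norm.shape
    modes = np.full((h, w), np.nan)
    for r in range(h):
        for c in range(w):
            if not valid[r, c]:
                continue
            r0, r1 = max(r - sp, 0), min(r + sp + 1, h)
            c0, c1 = max(c - sp, 0), min(c + sp + 1, w)
            win = norm[r0:r1, c0:c1].astype(float)
            wv = valid[r0:r1, c0:c1]
            y = float(norm[r, c])
            for _ in range(max_iter):
                sel = wv & (np.abs(win - y) <= sr)
                if not sel.any():
                    break
                ynew = float(win[sel].mean())
                shift = abs(ynew - y)
                y = ynew
                if shift <= eps:
                    break
            modes[r, c] = y
    return modes


def group_modes_bruteforce(modes, valid, sr):
    """BFS over 4-neighbours whose converged modes differ by <= sr."""
    h, w = modes.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 1
    for r in range(h):
        for c in range(w):
            if not valid[r, c] or labels[r, c]:
                continue
            stack = [(r, c)]
            labels[r, c] = nxt
            while stack:
                rr, cc = stack.pop()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < h and 0 <= c2 < w and valid[r2, c2]
                            and not labels[r2, c2]
                            and abs(modes[rr, cc] - modes[r2, c2]) <= sr):
                        labels[r2, c2] = nxt
                        stack.append((r2, c2))
            nxt += 1
    return labels


def scatter_points_bruteforce(u, v, mask, min_field_mag):
    """Literal evaluation of the divergence scatter-point conditions."""

    def sgn(x):
        return 1 if x > 0 else (-1 if x < 0 else 0)

    h, w = u.shape
    psx, psy = set(), set()
    for j in range(h - 1):
        for i in range(w - 1):
            if not mask[j, i]:
                continue
            mags = (np.hypot(u[j, i], v[j, i]),
                    np.hypot(u[j, i + 1], v[j, i + 1]),
                    np.hypot(u[j + 1, i], v[j + 1, i]))
            if max(mags) < min_field_mag:
                continue
            if (u[j, i] <= u[j, i + 1]
                    and abs(sgn(u[j, i]) + sgn(u[j, i + 1])) <= 1):
                psx.add((i, j))
            if (v[j, i] <= v[j + 1, i]
                    and abs(sgn(v[j, i]) + sgn(v[j + 1, i])) <= 1):
                psy.add((i, j))
    return psx & psy, psx, psy


def partitions_equal(a, b):
    """True when two label maps define the same partition (ignoring names).

    Label 0 must coincide exactly; positive labels may be permuted.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or not np.array_equal(a == 0, b == 0):
        return False
    fwd, bwd = {}, {}
    for x, y in zip(a.ravel(), b.ravel()):
        if x == 0:
            continue
        if fwd.setdefault(x, y) != y or bwd.setdefault(y, x) != x:
            return False
    return True


def plateau_image(rng, h, w, depths, noise_sd):
    """Random vertical/horizontal plateaus at the given depth levels."""
    n = len(depths)
    axis = rng.integers(0, 2)
    size = w if axis == 0 else h
    cuts = np.sort(rng.choice(np.arange(4, size - 4), size=n - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [size]])
    img = np.zeros((h, w), dtype=np.float64)
    for k, d in enumerate(depths):
        if axis == 0:
            img[:, bounds[k]:bounds[k + 1]] = d
        else:
            img[bounds[k]:bounds[k + 1], :] = d
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 1, 65535).astype(np.uint16)
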