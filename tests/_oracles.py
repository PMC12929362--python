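"""Independent oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: RMSD via the
quaternion (Horn) eigenvalue method instead of the SVD-based Kabsch
solution, and plateau detection via a naive exhaustive window scan instead
of the vectorized suffix accumulation.
"""

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray,
                    weights=None) -> float:
    """Optimal superposition RMSD via the quaternion eigenvalue method."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    n = len(mobile)
    w = np.full(n, 1.0) if weights is None else np.asarray(weights, float)
    wsum = w.sum()
    p = mobile - (w[:, None] * mobile).sum(0) / wsum
    q = reference - (w[:, None] * reference).sum(0) / wsum

    # correlation matrix and Horn's 4x4 key matrix
    m = (w[:, None] * p).T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key)[-1]
    gp = float((w * (p ** 2).sum(1)).sum())
    gq = float((w * (q ** 2).sum(1)).sum())
    msd = max(0.0, (gp + gq - 2.0 * lam) / wsum)
    return float(np.sqrt(msd))


def exhaustive_plateau_onset(times, values, window, slope_tol,
                             fluctuation_tol):
    """Naive double-loop plateau-onset scan (definition as stated)."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    starts = [i for i in range(len(times)) if times[i] <= times[-1] - window]
    for i in starts:
        ok = True
        for j in starts:
            if times[j] < times[i]:
                continue
            sel = (times >= times[j]) & (times <= times[j] + window)
            t_w, v_w = times[sel], values[sel]
            if len(t_w) < 2:
                ok = False
                break
            slope = np.polyfit(t_w, v_w, 1)[0]
            if abs(slope) > slope_tol or v_w.std(ddof=1) > fluctuation_tol:
                ok = False
                break
        if ok:
            return float(times[i])
    return None


def charwise_u_to_t(seq: str) -> str:
    """Per-character substitution map, independent of the library routine."""
    table = {"U": "T", "u": "t"}
    return "".join(table.get(ch, ch) for ch in seq)
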