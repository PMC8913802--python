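"""Numba kernels for the SC model's Metropolis-within-Gibbs sampler.

Because the encounter rate Lambda_j is constant across nights, the Poisson
likelihood depends on the data only through per-detector totals n_j (counts
summed over unmasked nights) and effective night counts k_j; every kernel
works on that sufficient reduction. The kernels maintain two derived arrays:

    R[i, j] = exp(-d(s_i, x_j)^2 / (2 sigma^2))   (all M rows, z=0 included)
    T[j]    = sum_i z_i R[i, j]                    so Lambda_j = lambda0 T[j]

All randomness uses numba's np.random state; callers seed it with
``set_seed`` (each chain seeds once at its start), which makes whole chains
bit-reproducible.
"""

import numpy as np
from numba import njit

# sigma prior kinds
SIGMA_UNIFORM = 0
SIGMA_GAMMA = 1


@njit(cache=True)
def set_seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def kernel_row(x, y, det_x, det_y, sigma, out):
    inv = 1.0 / (2.0 * sigma * sigma)
    for j in range(det_x.shape[0]):
        dd = (x - det_x[j]) ** 2 + (y - det_y[j]) ** 2
        out[j] = np.exp(-dd * inv)


@njit(cache=True)
def compute_R(sx, sy, det_x, det_y, sigma, R):
    for i in range(sx.shape[0]):
        kernel_row(sx[i], sy[i], det_x, det_y, sigma, R[i])


@njit(cache=True)
def compute_T(z, R, T):
    M, J = R.shape
    for j in range(J):
        T[j] = 0.0
    for i in range(M):
        if z[i] == 1:
            for j in range(J):
                T[j] += R[i, j]


@njit(cache=True)
def loglik_from_T(T, lambda0, n_j, k_j):
    """Unnormalised log-likelihood sum_j [n_j log(lambda0 T_j) - k_j lambda0 T_j]."""
    ll = 0.0
    for j in range(T.shape[0]):
        lam = lambda0 * T[j]
        ll -= lam * k_j[j]
        if n_j[j] > 0.0:
            if lam <= 0.0:
                return -np.inf
            ll += n_j[j] * np.log(lam)
    return ll


@njit(cache=True)
def update_z(z, R, T, lambda0, psi, n_j, k_j):
    """Single-site Gibbs sweep over the inclusion flags.

    Each z_i is drawn from its exact Bernoulli full conditional; T is kept
    consistent incrementally.
    """
    M, J = R.shape
    for i in range(M):
        if psi <= 0.0:
            a = -np.inf
        elif psi >= 1.0:
            a = np.inf
        else:
            a = np.log(psi) - np.log(1.0 - psi)
        if lambda0 > 0.0 and np.isfinite(a):
            for j in range(J):
                rij = R[i, j]
                if z[i] == 1:
                    t0 = T[j] - rij
                    if t0 < 0.0:
                        t0 = 0.0
                else:
                    t0 = T[j]
                a -= lambda0 * rij * k_j[j]
                if n_j[j] > 0.0:
                    t1 = t0 + rij
                    if t0 <= 0.0:
                        if t1 > 0.0:
                            a = np.inf
                            break
                        # both rates zero: impossible either way, ratio 1
                    else:
                        a += n_j[j] * (np.log(t1) - np.log(t0))
        if a == np.inf:
            p1 = 1.0
        elif a == -np.inf:
            p1 = 0.0
        else:
            p1 = 1.0 / (1.0 + np.exp(-a))
        znew = 1 if np.random.random() < p1 else 0
        if znew != z[i]:
            if znew == 1:
                for j in range(J):
                    T[j] += R[i, j]
            else:
                for j in range(J):
                    T[j] -= R[i, j]
            z[i] = znew


@njit(cache=True)
def update_s(z, sx, sy, R, T, lambda0, n_j, k_j, det_x, det_y, sigma,
             xmin, xmax, ymin, ymax, step):
    """Activity-centre moves: random walk for z=1, uniform redraw for z=0.

    Proposals outside the state-space are rejected outright (uniform prior
    on S). Returns (accepted, proposed) counts among z=1 individuals for
    proposal-scale adaptation.
    """
    M, J = R.shape
    r_new = np.empty(J)
    acc = 0
    n_try = 0
    for i in range(M):
        if z[i] == 0:
            sx[i] = np.random.uniform(xmin, xmax)
            sy[i] = np.random.uniform(ymin, ymax)
            kernel_row(sx[i], sy[i], det_x, det_y, sigma, R[i])
            continue
        n_try += 1
        px = sx[i] + step * np.random.normal()
        py = sy[i] + step * np.random.normal()
        if px < xmin or px > xmax or py < ymin or py > ymax:
            continue
        kernel_row(px, py, det_x, det_y, sigma, r_new)
        dll = 0.0
        if lambda0 > 0.0:
            for j in range(J):
                t1 = T[j] - R[i, j] + r_new[j]
                if t1 < 0.0:
                    t1 = 0.0
                dll -= lambda0 * (t1 - T[j]) * k_j[j]
                if n_j[j] > 0.0:
                    if t1 <= 0.0 and T[j] <= 0.0:
                        pass
                    elif t1 <= 0.0:
                        dll = -np.inf
                        break
                    elif T[j] <= 0.0:
                        dll = np.inf
                        break
                    else:
                        dll += n_j[j] * (np.log(t1) - np.log(T[j]))
        if dll >= 0.0 or np.log(np.random.random()) < dll:
            for j in range(J):
                T[j] += r_new[j] - R[i, j]
                R[i, j] = r_new[j]
            sx[i] = px
            sy[i] = py
            acc += 1
    return acc, n_try


@njit(cache=True)
def update_lambda0(lambda0, T, n_j, k_j, lo, hi, step):
    """Log-scale random-walk Metropolis for the baseline encounter rate.

    Uniform(lo, hi) prior; the log-scale move contributes a Jacobian factor
    lambda0'/lambda0 and keeps proposals strictly positive.
    """
    lam_new = lambda0 * np.exp(step * np.random.normal())
    if lam_new <= lo or lam_new >= hi:
        return lambda0, 0
    dll = np.log(lam_new) - np.log(lambda0)  # Jacobian
    for j in range(T.shape[0]):
        dll -= (lam_new - lambda0) * T[j] * k_j[j]
        if n_j[j] > 0.0:
            dll += n_j[j] * (np.log(lam_new) - np.log(lambda0))
    if dll >= 0.0 or np.log(np.random.random()) < dll:
        return lam_new, 1
    return lambda0, 0


@njit(cache=True)
def update_sigma(sigma, z, sx, sy, R, T, lambda0, n_j, k_j, det_x, det_y,
                 prior_kind, p1, p2, step, r_buf, t_buf):
    """Log-scale random-walk Metropolis for the movement scale sigma.

    prior_kind SIGMA_UNIFORM: Uniform(p1, p2); SIGMA_GAMMA: Gamma(shape=p1,
    rate=p2). A sigma move changes every R entry, so the full matrix is
    recomputed into scratch buffers and swapped in on acceptance.
    """
    M, J = R.shape
    s_new = sigma * np.exp(step * np.random.normal())
    if prior_kind == SIGMA_UNIFORM:
        if s_new <= p1 or s_new >= p2:
            return sigma, 0
        lprior = 0.0
    else:
        lprior = (p1 - 1.0) * (np.log(s_new) - np.log(sigma)) - p2 * (s_new - sigma)
    compute_R(sx, sy, det_x, det_y, s_new, r_buf)
    compute_T(z, r_buf, t_buf)
    dll = lprior + (np.log(s_new) - np.log(sigma))  # prior + Jacobian
    if lambda0 > 0.0:
        for j in range(J):
            dll -= lambda0 * (t_buf[j] - T[j]) * k_j[j]
            if n_j[j] > 0.0:
                if t_buf[j] <= 0.0 and T[j] <= 0.0:
                    pass
                elif t_buf[j] <= 0.0:
                    dll = -np.inf
                    break
                elif T[j] <= 0.0:
                    dll = np.inf
                    break
                else:
                    dll += n_j[j] * (np.log(t_buf[j]) - np.log(T[j]))
    if dll >= 0.0 or np.log(np.random.random()) < dll:
        for i in range(M):
            for j in range(J):
                R[i, j] = r_buf[i, j]
        for j in range(J):
            T[j] = t_buf[j]
        return s_new, 1
    return sigma, 0


@njit(cache=True)
def update_psi(z, psi_a, psi_b):
    """Exact conjugate draw psi ~ Beta(a + sum z, b + M - sum z)."""
    M = z.shape[0]
    n1 = 0
    for i in range(M):
        n1 += z[i]
    return np.random.beta(psi_a + n1, psi_b + M - n1)


@njit(cache=True)
def run_chain(seed, det_x, det_y, n_j, k_j, M,
              xmin, xmax, ymin, ymax,
              lam_lo, lam_hi, psi_a, psi_b,
              sigma_prior_kind, sigma_p1, sigma_p2,
              n_iter, n_burn, n_adapt, thin, snapshot_every,
              init_lambda0, init_sigma,
              step_s, step_l, step_g):
    """One complete chain. Returns retained draws and z/s snapshots.

    The first n_adapt iterations tune the three proposal scales by
    Robbins-Monro batches of 50 toward acceptance ~0.3 (within the 0.2-0.45
    band); scales are frozen afterwards so the post-adaptation kernel
    satisfies detailed balance. Retention starts after n_burn; snapshots are
    taken every snapshot_every-th retained iteration.
    """
    np.random.seed(seed)
    J = det_x.shape[0]
    z = np.zeros(M, dtype=np.int8)
    sx = np.empty(M)
    sy = np.empty(M)
    for i in range(M):
        if np.random.random() < 0.5:
            z[i] = 1
        sx[i] = np.random.uniform(xmin, xmax)
        sy[i] = np.random.uniform(ymin, ymax)
    lambda0 = init_lambda0
    sigma = init_sigma
    psi = 0.5
    R = np.empty((M, J))
    T = np.empty(J)
    r_buf = np.empty((M, J))
    t_buf = np.empty(J)
    compute_R(sx, sy, det_x, det_y, sigma, R)
    compute_T(z, R, T)

    n_keep = (n_iter - n_burn + thin - 1) // thin
    draws = np.empty((n_keep, 4))  # N, lambda0, sigma, psi
    n_snap = (n_keep + snapshot_every - 1) // snapshot_every
    snap_iter = np.empty(n_snap, dtype=np.int64)
    snap_x = np.empty((n_snap, M))
    snap_y = np.empty((n_snap, M))
    snap_z = np.empty((n_snap, M), dtype=np.int8)

    acc_s = 0
    try_s = 0
    acc_l = 0
    try_l = 0
    acc_g = 0
    try_g = 0
    batch = 0
    kept = 0
    taken = 0
    for it in range(n_iter):
        compute_T(z, R, T)  # refresh against incremental drift
        update_z(z, R, T, lambda0, psi, n_j, k_j)
        psi = update_psi(z, psi_a, psi_b)
        a, t = update_s(z, sx, sy, R, T, lambda0, n_j, k_j, det_x, det_y,
                        sigma, xmin, xmax, ymin, ymax, step_s)
        acc_s += a
        try_s += t
        lambda0, a = update_lambda0(lambda0, T, n_j, k_j, lam_lo, lam_hi, step_l)
        acc_l += a
        try_l += 1
        sigma, a = update_sigma(sigma, z, sx, sy, R, T, lambda0, n_j, k_j,
                                det_x, det_y, sigma_prior_kind, sigma_p1,
                                sigma_p2, step_g, r_buf, t_buf)
        acc_g += a
        try_g += 1
        if it < n_adapt and (it + 1) % 50 == 0:
            batch += 1
            gain = 1.0 / np.sqrt(batch)
            if try_s > 0:
                step_s *= np.exp(gain * (acc_s / try_s - 0.3))
            step_l *= np.exp(gain * (acc_l / try_l - 0.3))
            step_g *= np.exp(gain * (acc_g / try_g - 0.3))
            # keep scales in a sane range
            if step_s < 1e-3:
                step_s = 1e-3
            if step_l < 1e-4:
                step_l = 1e-4
            if step_g < 1e-4:
                step_g = 1e-4
            acc_s = 0
            try_s = 0
            acc_l = 0
            try_l = 0
            acc_g = 0
            try_g = 0
        if it >= n_burn and (it - n_burn) % thin == 0:
            nsum = 0
            for i in range(M):
                nsum += z[i]
            draws[kept, 0] = nsum
            draws[kept, 1] = lambda0
            draws[kept, 2] = sigma
            draws[kept, 3] = psi
            if kept % snapshot_every == 0:
                snap_iter[taken] = it
                for i in range(M):
                    snap_x[taken, i] = sx[i]
                    snap_y[taken, i] = sy[i]
                    snap_z[taken, i] = z[i]
                taken += 1
            kept += 1
    steps = np.array([step_s, step_l, step_g])
    acc_rates = np.array([
        acc_s / try_s if try_s > 0 else np.nan,
        acc_l / try_l if try_l > 0 else np.nan,
        acc_g / try_g if try_g > 0 else np.nan,
    ])
    return draws, snap_iter, snap_x, snap_y, snap_z, steps, acc_rates
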