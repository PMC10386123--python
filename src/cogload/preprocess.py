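"""Signal preprocessing: band-pass filtering, PPG beat detection, EDA decomposition.

The EDA decomposition models observed skin conductance as

    y = tonic + phasic + residual,
    tonic  = cubic-spline baseline (knots every ``knot_spacing`` s) + linear drift,
    phasic = h * q  (bi-exponential kernel convolved with a sparse driver q >= 0),

and recovers the components by solving the convex program

    minimize  0.5 * ||y - tonic - phasic||^2  +  alpha * sum(q)  +  gamma * ||l||^2
    subject to q >= 0,

where ``l`` are the spline coefficients.  The driver ``q`` is the sudomotor
nerve activity (SMNA) estimate.  The bi-exponential kernel is represented in
ARMA form (tridiagonal operators on a latent state), and the program is
solved by ADMM with one cached sparse factorisation per chunk; long signals
are solved in overlapping chunks and stitched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, linalg, signal, sparse
import scipy.sparse.linalg  # noqa: F401  (registers sparse.linalg.splu)

DEFAULT_FS = 51.2

# Bi-exponential SCR kernel time constants (s); shared with the synthetic
# generator so recovery tests are self-consistent.
TAU_RISE = 0.7
TAU_DECAY = 2.0


class ParameterError(ValueError):
    """Invalid filter or solver parameters."""


class SolverError(RuntimeError):
    """EDA decomposition failed to converge."""


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass(x, low, high, order=4, fs=DEFAULT_FS):
    """Zero-phase Butterworth band-pass filter.

    Forward-backward filtering is used so peak timing is not shifted; note the
    effective attenuation is twice that of a single order-``order`` pass.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < low < high < fs / 2):
        raise ParameterError(
            f"invalid band ({low}, {high}) for fs={fs}: need 0 < low < high < fs/2"
        )
    sos = signal.butter(order, [low, high], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def accel_magnitude(ax, ay, az):
    """Elementwise Euclidean norm of the three (filtered) accelerometer axes."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError("accelerometer axes must have equal length")
    return np.sqrt(ax**2 + ay**2 + az**2)


def filtered_accel_magnitude(ax, ay, az, fs=DEFAULT_FS, low=0.5, high=6.0, order=4):
    """Band-pass each axis (removes gravity), then take the magnitude."""
    return accel_magnitude(
        bandpass(ax, low, high, order, fs),
        bandpass(ay, low, high, order, fs),
        bandpass(az, low, high, order, fs),
    )


# ---------------------------------------------------------------------------
# PPG beat detection
# ---------------------------------------------------------------------------

@dataclass
class BeatSeries:
    """Candidate PPG peaks with sequential inter-beat-interval acceptance.

    ``peak_indices``/``accepted`` cover every candidate peak.  ``ibi``/``hr``
    hold one entry per accepted beat interval: ``hr = 60 / ibi``.
    ``hr_times`` is the time (s) of the closing peak of each accepted interval.
    """

    peak_indices: np.ndarray
    peak_times: np.ndarray        # sub-sample refined, seconds
    accepted: np.ndarray
    ibi: np.ndarray
    hr: np.ndarray
    hr_times: np.ndarray
    fs: float

    def __len__(self):
        return len(self.peak_indices)

    @property
    def accepted_times(self):
        return self.peak_times[self.accepted]

    def shifted(self, dt_s):
        """Same series on a clock shifted so old time ``dt_s`` becomes 0."""
        return BeatSeries(
            peak_indices=self.peak_indices - int(round(dt_s * self.fs)),
            peak_times=self.peak_times - dt_s,
            accepted=self.accepted,
            ibi=self.ibi, hr=self.hr, hr_times=self.hr_times - dt_s,
            fs=self.fs,
        )

    def slice(self, start_s, end_s):
        """Restrict the accepted-beat series to [start_s, end_s)."""
        m_peaks = (self.peak_times >= start_s) & (self.peak_times < end_s)
        m_hr = (self.hr_times >= start_s) & (self.hr_times < end_s)
        return BeatSeries(
            peak_indices=self.peak_indices[m_peaks],
            peak_times=self.peak_times[m_peaks],
            accepted=self.accepted[m_peaks],
            ibi=self.ibi[m_hr],
            hr=self.hr[m_hr],
            hr_times=self.hr_times[m_hr],
            fs=self.fs,
        )


def _empty_beats(fs):
    z = np.array([], dtype=float)
    return BeatSeries(
        peak_indices=np.array([], dtype=int),
        peak_times=z,
        accepted=np.array([], dtype=bool),
        ibi=z, hr=z, hr_times=z, fs=fs,
    )


def _refine_peak_times(x, peaks, fs):
    """Quadratic-interpolation sub-sample peak times."""
    t = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(x) - 1)
    p = peaks[inner]
    y0, y1, y2 = x[p - 1], x[p], x[p + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    t[inner] = p + np.clip(delta, -0.5, 0.5)
    return t / fs


def detect_beats(ppg_filtered, fs=DEFAULT_FS, hr_max=180.0, tolerance=0.10,
                 prominence_frac=0.3):
    """Detect heartbeats in a filtered PPG signal.

    Candidate peaks are local maxima separated by at least ``60/hr_max`` s with
    prominence above ``prominence_frac`` times the 95th percentile of ``|x|``.
    A candidate interval is accepted when it deviates from the reference
    interval by at most ``tolerance`` (10%); the reference is seeded with the
    median of the first five candidate intervals, is updated on every
    acceptance, and is left unchanged by rejections.  A peak counts as a
    heartbeat when at least one of its adjacent intervals is accepted, so a
    single ectopic peak costs only its own intervals.
    """
    x = np.asarray(ppg_filtered, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return _empty_beats(fs)
    distance = max(1, int(round(fs * 60.0 / hr_max)))
    prominence = prominence_frac * np.percentile(np.abs(x), 95)
    peaks, _ = signal.find_peaks(x, distance=distance, prominence=prominence or None)
    if len(peaks) < 2:
        return _empty_beats(fs)

    t = _refine_peak_times(x, peaks, fs)
    d = np.diff(t)
    ref = float(np.median(d[:5]))
    accepted = np.zeros(len(peaks), dtype=bool)
    ibi, hr, hr_times = [], [], []
    for i, di in enumerate(d):
        if abs(di - ref) <= tolerance * ref:
            accepted[i] = accepted[i + 1] = True
            ibi.append(di)
            hr.append(60.0 / di)
            hr_times.append(t[i + 1])
            ref = di
        # a rejected interval does not update the reference; its peaks are
        # only heartbeats if a neighbouring interval accepts them
    return BeatSeries(
        peak_indices=peaks,
        peak_times=t,
        accepted=accepted,
        ibi=np.asarray(ibi),
        hr=np.asarray(hr),
        hr_times=np.asarray(hr_times),
        fs=fs,
    )


# ---------------------------------------------------------------------------
# EDA decomposition
# ---------------------------------------------------------------------------

def scr_kernel(fs, tau_rise=TAU_RISE, tau_decay=TAU_DECAY, duration=None):
    """Peak-normalised bi-exponential SCR kernel sampled at ``fs``."""
    if duration is None:
        duration = 8.0 * tau_decay
    t = np.arange(0.0, duration, 1.0 / fs)
    h = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return h / h.max()


@dataclass
class EdaDecomposition:
    """Tonic/phasic/driver split of a skin-conductance signal.

    ``tonic + phasic + residual`` reconstructs the input exactly (the residual
    is defined as the remainder).  ``smna`` is the nonnegative sparse driver.
    """

    tonic: np.ndarray
    phasic: np.ndarray
    smna: np.ndarray
    residual: np.ndarray
    solver_status: str = "converged"
    fs: float = DEFAULT_FS
    objective: float = field(default=np.nan)


def _spline_basis(n, fs, knot_spacing):
    """Sparse cubic B-spline design matrix with knots every ``knot_spacing`` s."""
    t = np.arange(n) / fs
    t_end = t[-1] if n > 1 else 1.0 / fs
    n_int = max(int(np.floor(t_end / knot_spacing)) - 1, 0)
    interior = (np.arange(1, n_int + 1) * knot_spacing) if n_int else np.array([])
    knots = np.r_[[0.0] * 4, interior, [t_end] * 4]
    return sparse.csr_matrix(interpolate.BSpline.design_matrix(t, knots, 3))


def _arma_operators(n, fs, tau_rise, tau_decay):
    """Tridiagonal driver/phasic operators of the discretised SCR dynamics.

    The continuous transfer function ``1 / ((tau_r s + 1)(tau_d s + 1))`` is
    discretised with the bilinear transform, giving ``phasic = M u`` and
    ``driver = A u`` for a state ``u`` with tridiagonal ``M`` and ``A``.
    ``A`` is scaled so the implied discrete kernel has unit peak, i.e. driver
    amplitudes are on the scale of SCR amplitudes (uS).

    Returns ``(A, M, ab)`` with ``ab`` the (2, n) banded form of ``A`` for
    :func:`scipy.linalg.solve_banded`.
    """
    dt = 1.0 / fs
    cr, cd = 2.0 * tau_rise / dt, 2.0 * tau_decay / dt
    d0 = (cr + 1.0) * (cd + 1.0)
    d1 = 2.0 * (1.0 - cr * cd)
    d2 = (1.0 - cr) * (1.0 - cd)
    # unit-impulse response peak, for normalisation
    m = max(8, min(n, int(10 * tau_decay * fs)))
    ab0 = np.zeros((3, m))
    ab0[0], ab0[1, :-1], ab0[2, :-2] = d0, d1, d2
    e = np.zeros(m)
    e[0] = 1.0
    u = linalg.solve_banded((2, 0), ab0, e)
    peak = float(np.convolve(u, [1.0, 2.0, 1.0])[:m].max())
    d0, d1, d2 = d0 * peak, d1 * peak, d2 * peak
    A = sparse.diags([np.full(n, d0), np.full(n - 1, d1), np.full(n - 2, d2)],
                     [0, -1, -2], format="csc")
    M = sparse.diags([np.full(n, 1.0), np.full(n - 1, 2.0), np.full(n - 2, 1.0)],
                     [0, -1, -2], format="csc")
    ab = np.zeros((3, n))
    ab[0], ab[1, :-1], ab[2, :-2] = d0, d1, d2
    return A, M, ab


def phasic_from_driver(q, fs, tau_rise=TAU_RISE, tau_decay=TAU_DECAY):
    """Phasic signal implied by a driver, via the discretised SCR dynamics."""
    n = len(q)
    _, M, ab = _arma_operators(n, fs, tau_rise, tau_decay)
    u = linalg.solve_banded((2, 0), ab, np.asarray(q, dtype=float))
    return M @ u


def _solve_qp(y, fs, alpha, gamma, knot_spacing, tau_rise, tau_decay,
              rho=0.1, maxiter=4000, tol=1e-8):
    """Solve one decomposition chunk at rate ``fs`` by ADMM.

    Variables are the ARMA state ``u``, spline coefficients ``l`` and drift
    ``d``; the nonnegativity and l1 penalty act on the driver ``A u`` through
    an ADMM split with a cached sparse factorisation (one per chunk).
    Returns ``(q, tonic, phasic, status, obj)``.
    """
    n = len(y)
    A, M, ab = _arma_operators(n, fs, tau_rise, tau_decay)
    B = _spline_basis(n, fs, knot_spacing)
    t = np.arange(n) / fs
    C = sparse.csc_matrix(np.column_stack([np.ones(n), t / max(t[-1], 1.0)]))
    nl = B.shape[1]
    nvar = n + nl + 2
    E = sparse.hstack([M, B, C], format="csc")          # reconstruction
    G = sparse.hstack([A, sparse.csc_matrix((n, nl + 2))], format="csc")
    Gam = sparse.diags(np.r_[np.zeros(n), 2.0 * gamma * np.ones(nl), np.zeros(2)])
    EtE = (E.T @ E + Gam).tocsc()
    GtG = (G.T @ G).tocsc()
    lu = sparse.linalg.splu((EtE + rho * GtG).tocsc())
    Ety = E.T @ y
    Gt = G.T.tocsc()

    x = np.zeros(nvar)
    s = np.zeros(n)
    w = np.zeros(n)
    relax = 1.7
    sqrt_n = np.sqrt(n)
    status = f"not converged in {maxiter} iterations"
    for it in range(maxiter):
        x = lu.solve(Ety + rho * (Gt @ (s - w)))
        gx = G @ x
        gxr = relax * gx + (1.0 - relax) * s
        s_old = s
        s = np.maximum(gxr + w - alpha / rho, 0.0)
        w = w + gxr - s
        if it % 25 == 24:
            rp = np.linalg.norm(gx - s) / sqrt_n
            rd = rho * np.linalg.norm(s - s_old) / sqrt_n
            if rp < tol and rd < tol:
                status = "converged"
                break
            # residual balancing keeps the penalty in a productive range
            if rp > 10.0 * rd:
                scale = 2.0
            elif rd > 10.0 * rp:
                scale = 0.5
            else:
                continue
            rho *= scale
            w /= scale   # scaled dual variable tracks 1/rho
            lu = sparse.linalg.splu((EtE + rho * GtG).tocsc())

    q = s
    u = linalg.solve_banded((2, 0), ab, q)     # phasic consistent with driver
    phasic = M @ u
    tonic = B @ x[n:n + nl] + C @ x[n + nl:]
    resid = y - tonic - phasic
    obj = float(0.5 * resid @ resid + alpha * q.sum()
                + gamma * (x[n:n + nl] ** 2).sum())
    return q, tonic, phasic, status, obj


def decompose_eda(gsr, fs=DEFAULT_FS, *, alpha=8e-4, gamma=1e-2,
                  knot_spacing=10.0, tau_rise=TAU_RISE, tau_decay=TAU_DECAY,
                  fs_qp=12.8, chunk_s=300.0, chunk_overlap_s=20.0,
                  check_convergence=True):
    """Decompose a skin-conductance signal into tonic, phasic, and SMNA driver.

    The signal is block-averaged down to ``fs_qp`` for the optimisation and the
    components are linearly interpolated back to the input rate; the residual
    is then the exact remainder, so ``tonic + phasic + residual == gsr``.

    Raises
    ------
    ValueError
        If the input contains non-finite or negative values.
    SolverError
        If the optimiser fails to converge and ``check_convergence`` is set.
    """
    y_full = np.asarray(gsr, dtype=float)
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if not np.all(np.isfinite(y_full)):
        raise ValueError("GSR contains non-finite values")
    if np.any(y_full < 0):
        raise ValueError("GSR contains negative values")
    n_full = len(y_full)
    if n_full == 0:
        raise ValueError("empty signal")

    # Block-average decimation keeps lengths exact for integer rate ratios.
    r = max(1, int(round(fs / fs_qp)))
    fs_d = fs / r
    n_d = n_full // r
    if n_d < 8:
        raise ValueError("signal too short to decompose")
    y = y_full[: n_d * r].reshape(n_d, r).mean(axis=1)

    q_d = np.zeros(n_d)
    tonic_d = np.zeros(n_d)
    phasic_d = np.zeros(n_d)
    statuses = []

    chunk_n = int(round(chunk_s * fs_d))
    overlap_n = int(round(chunk_overlap_s * fs_d))
    if n_d <= chunk_n + overlap_n:
        spans = [(0, n_d, 0, n_d)]
    else:
        spans = []
        start = 0
        while start < n_d:
            lo = max(0, start - overlap_n)
            hi = min(n_d, start + chunk_n + overlap_n)
            spans.append((lo, hi, start, min(n_d, start + chunk_n)))
            start += chunk_n

    for lo, hi, keep_lo, keep_hi in spans:
        q, tonic, phasic, status, _ = _solve_qp(
            y[lo:hi], fs_d, alpha, gamma, knot_spacing, tau_rise, tau_decay)
        statuses.append(status)
        q_d[keep_lo:keep_hi] = q[keep_lo - lo:keep_hi - lo]
        tonic_d[keep_lo:keep_hi] = tonic[keep_lo - lo:keep_hi - lo]
        phasic_d[keep_lo:keep_hi] = phasic[keep_lo - lo:keep_hi - lo]

    status = "converged" if all(s == "converged" for s in statuses) else \
        next(s for s in statuses if s != "converged")
    if check_convergence and status != "converged":
        raise SolverError(status)

    # Upsample components to the input rate; residual is the exact remainder.
    t_d = (np.arange(n_d) + 0.5) * r / fs
    t_full = np.arange(n_full) / fs
    tonic = np.interp(t_full, t_d, tonic_d)
    phasic = np.interp(t_full, t_d, phasic_d)
    # nearest-block upsampling keeps the driver exactly sparse
    smna = np.repeat(q_d, r)[:n_full]
    if len(smna) < n_full:
        smna = np.r_[smna, np.full(n_full - len(smna), q_d[-1])]
    np.clip(phasic, 0.0, None, out=phasic)
    np.clip(smna, 0.0, None, out=smna)
    residual = y_full - tonic - phasic
    return EdaDecomposition(
        tonic=tonic, phasic=phasic, smna=smna, residual=residual,
        solver_status=status, fs=fs,
    )


def smna_event_count(smna, fs, threshold=0.01, min_separation_s=1.0):
    """Number of driver excursions above ``threshold`` separated by >= 1 s."""
    above = np.asarray(smna) > threshold
    if not above.any():
        return 0
    idx = np.flatnonzero(above)
    gaps = np.diff(idx) / fs
    return int(1 + np.sum(gaps >= min_separation_s))
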