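"""Multi-time-origin correlation functions and the observables built on them.

Three observables share one engine (:func:`correlate`):

* the continuous hydrogen-bond time correlation function
  S_HB(t) = <h(0) H(t)> / <h(0)^2>, where h is the instantaneous bonded
  indicator and H requires the bond to persist at every intermediate frame
  (the Rapaport "continuous" definition); its time integral is the HB
  lifetime tau_HB;
* the first-order Legendre dipole correlation C1(t) = <mu(0).mu(t)>, whose
  long-time decay is fit by a*exp(-t/tau1)+b*exp(-t/tau2) with the
  reorientation time tau_reor = (a tau1 + b tau2)/(a + b);
* the vibrational density of states, the Fourier transform of the
  (per-species) velocity autocorrelation function.

Averages run over entities (pairs / molecules / atoms) and over multiple,
possibly overlapping, time origins within a fixed window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .traj_io import Trajectory, WaterTopology, minimum_image_displacement
from .structure import HBCriteria, detect_hbonds

__all__ = [
    "CorrelationFunction",
    "BiExpFit",
    "VDOSSpectrum",
    "correlate",
    "continuous_hb_tcf",
    "hb_lifetime",
    "dipole_vectors",
    "dipole_tcf",
    "fit_biexponential",
    "vdos",
    "vacf_spectrum",
]

#: speed of light in cm/ps (converts cycles/ps to wavenumber in cm^-1)
_C_CM_PER_PS = 0.0299792458


@dataclass
class CorrelationFunction:
    """A lag grid (ps), correlation values, and per-lag origin counts."""

    lags: np.ndarray
    values: np.ndarray
    n_origins: np.ndarray
    window: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_origins = np.asarray(self.n_origins)


@dataclass
class BiExpFit:
    """Result of the bi-exponential fit of C1(t) (times in ps)."""

    a: float
    b: float
    tau1: float
    tau2: float
    tau_reor: float
    fit_start: float
    residual_rms: float

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * np.exp(-t / self.tau1) + self.b * np.exp(-t / self.tau2)


@dataclass
class VDOSSpectrum:
    """Vibrational density of states per species (arbitrary units)."""

    wavenumbers: np.ndarray
    intensity: dict[str, np.ndarray]

    @property
    def total(self) -> np.ndarray:
        return self.intensity["total"]


def _origin_list(n_frames: int, n_lags: int, origin_stride: int) -> np.ndarray:
    last = n_frames - n_lags
    if last < 0:
        raise ValueError(
            f"window needs {n_lags} frames but the series has only {n_frames}"
        )
    return np.arange(0, last + 1, origin_stride)


def correlate(
    series: np.ndarray,
    dt: float,
    window: float,
    origin_stride: int = 1,
    kernel: str = "dot",
    origin_selection: np.ndarray | None = None,
    per_lag_origins: bool = False,
) -> CorrelationFunction:
    """Multi-time-origin correlation of a per-entity time series.

    Parameters
    ----------
    series : ndarray
        ``(n_frames, n_entities, 3)`` vectors for the ``dot`` kernel, or
        ``(n_frames, n_entities)`` 0/1 indicators for the ``survival``
        kernel.
    dt, window : float
        Frame spacing and correlation window, in ps.
    origin_stride : int
        Spacing between successive time origins, in frames.
    kernel : {"dot", "survival"}
        ``dot`` computes <u(0).u(t)>; ``survival`` computes
        <h(0) H(t)> / <h(0)^2> with H requiring continuity (the indicator
        must be 1 at every intermediate frame).
    origin_selection : ndarray of bool, optional
        ``(n_frames, n_entities)`` mask; an entity contributes from a given
        origin only if the mask is set at that origin frame (membership is
        evaluated at the origin and the entity is then followed across the
        whole window).
    per_lag_origins : bool
        With the default fixed-origin protocol every lag is averaged over
        the same origin set (origins must leave room for the full window),
        which makes the whole curve share one statistical basis but leaves
        most of the trajectory unused at short lags when the window is
        nearly as long as the run.  ``per_lag_origins=True`` instead
        averages each lag over every origin that fits it, which is the
        minimum-variance choice for curve fitting (dot kernel only).
    """
    series = np.asarray(series)
    if kernel not in ("dot", "survival"):
        raise ValueError(f"unknown kernel {kernel!r}")
    if kernel == "dot" and (series.ndim != 3 or series.shape[2] != 3):
        raise ValueError("dot kernel expects (n_frames, n_entities, 3)")
    if kernel == "survival" and series.ndim != 2:
        raise ValueError("survival kernel expects (n_frames, n_entities)")
    n_frames = series.shape[0]
    n_lags = int(round(window / dt)) + 1
    if per_lag_origins:
        if kernel != "dot":
            raise ValueError("per_lag_origins supports the dot kernel only")
        return _correlate_per_lag(
            series, dt, window, n_lags, origin_stride, origin_selection
        )
    origins = _origin_list(n_frames, n_lags, origin_stride)

    num_per_origin = np.zeros((origins.size, n_lags))
    weight_per_origin = np.zeros(origins.size)
    for oi, t0 in enumerate(origins):
        if kernel == "dot":
            u0 = series[t0]
            block = series[t0 : t0 + n_lags]
            if origin_selection is not None:
                mask = origin_selection[t0]
                u0 = u0[mask]
                block = block[:, mask]
            if u0.shape[0] == 0:
                continue
            # per-entity dots, then a single reduction over entities
            num_per_origin[oi] = np.sum(block * u0[None, :, :], axis=2).sum(axis=1)
            weight_per_origin[oi] = u0.shape[0]
        else:
            h0 = series[t0].astype(float)
            if origin_selection is not None:
                h0 = h0 * origin_selection[t0]
            w = float(h0.sum())
            if w == 0:
                continue
            block = series[t0 : t0 + n_lags].astype(float)
            alive = np.cumprod(block, axis=0)  # continuity from the origin
            num_per_origin[oi] = (alive * h0[None, :]).sum(axis=1)
            weight_per_origin[oi] = w

    total_weight = weight_per_origin.sum()
    if total_weight == 0:
        raise ValueError("no entities selected at any time origin")
    values = np.sum(num_per_origin, axis=0) / total_weight
    contributed = np.count_nonzero(weight_per_origin)
    return CorrelationFunction(
        lags=np.arange(n_lags) * dt,
        values=values,
        n_origins=np.full(n_lags, contributed, dtype=int),
        window=window,
    )


def _correlate_per_lag(
    series: np.ndarray,
    dt: float,
    window: float,
    n_lags: int,
    origin_stride: int,
    origin_selection: np.ndarray | None,
) -> CorrelationFunction:
    n_frames = series.shape[0]
    if n_lags > n_frames:
        raise ValueError(
            f"window needs {n_lags} frames but the series has only {n_frames}"
        )
    if origin_selection is None:
        # all origins per lag == the FFT autocorrelation, summed over the
        # three components and all entities (origin_stride is moot: the
        # estimate already uses every origin)
        nfft = 1 << int(np.ceil(np.log2(2 * n_frames)))
        F = np.fft.rfft(series, n=nfft, axis=0)
        acf = np.fft.irfft(F * np.conj(F), n=nfft, axis=0)[:n_lags]
        num = acf.sum(axis=(1, 2))
        counts = np.arange(n_frames, n_frames - n_lags, -1)
        values = num / (counts * series.shape[1])
        return CorrelationFunction(
            lags=np.arange(n_lags) * dt, values=values,
            n_origins=counts, window=window,
        )
    values = np.empty(n_lags)
    counts = np.empty(n_lags, dtype=int)
    for lag in range(n_lags):
        t0 = np.arange(0, n_frames - lag, origin_stride)
        mask = origin_selection[t0]
        w = mask.sum()
        if w == 0:
            values[lag] = np.nan
            counts[lag] = 0
            continue
        prod = np.sum(series[t0] * series[t0 + lag], axis=2)
        values[lag] = float(np.sum(prod * mask) / w)
        counts[lag] = t0.size
    if np.isnan(values).all():
        raise ValueError("no entities selected at any time origin")
    return CorrelationFunction(
        lags=np.arange(n_lags) * dt, values=values, n_origins=counts, window=window
    )


def continuous_hb_tcf(
    traj: Trajectory,
    topology: WaterTopology,
    criteria: HBCriteria | None = None,
    window: float = 11.0,
    origin_stride: int = 1,
) -> CorrelationFunction:
    """Continuous HB survival S_HB(t) from per-frame geometric HB detection.

    A pair is identified by its (donor, acceptor) molecules; it is "alive"
    at lag t only if bonded at every frame from the origin through t.
    The default 11 ps window follows the multi-origin overlapping-interval
    protocol.
    """
    if criteria is None:
        criteria = HBCriteria()
    per_frame: list[set[tuple[int, int]]] = []
    universe: set[tuple[int, int]] = set()
    for f in range(traj.n_frames):
        bonds = detect_hbonds(traj.positions[f], topology, criteria, traj.cell[f])
        pairs = {(int(d), int(a)) for d, a, _ in bonds}
        per_frame.append(pairs)
        universe |= pairs
    if not universe:
        raise ValueError("no hydrogen bonds detected in any frame")
    index = {p: i for i, p in enumerate(sorted(universe))}
    h = np.zeros((traj.n_frames, len(index)), dtype=np.int8)
    for f, pairs in enumerate(per_frame):
        for p in pairs:
            h[f, index[p]] = 1
    return correlate(h, traj.dt, window, origin_stride=origin_stride, kernel="survival")


def hb_lifetime(S: CorrelationFunction, tail: str = "exp_extrapolate") -> float:
    """HB lifetime tau_HB as the time integral of S_HB(t).

    ``tail="exp_extrapolate"`` adds the analytic integral of a single
    exponential fitted (in log space) to the last 20% of the window, which
    corrects the truncation of slowly decaying survival curves;
    ``tail="none"`` integrates over the window only.
    """
    if tail not in ("none", "exp_extrapolate"):
        raise ValueError("tail must be 'none' or 'exp_extrapolate'")
    base = float(np.trapezoid(S.values, S.lags))
    if tail == "none":
        return base
    n = S.lags.size
    i0 = max(int(0.8 * n), 2)
    t_tail = S.lags[i0:]
    v_tail = S.values[i0:]
    pos = v_tail > 0
    if pos.sum() < 2 or v_tail[pos][0] < 1e-12:
        return base  # fully decayed inside the window; nothing to add
    coef = np.polyfit(t_tail[pos], np.log(v_tail[pos]), 1)
    slope = coef[0]
    if slope >= 0:
        return base
    tau_tail = -1.0 / slope
    s_end = float(np.exp(np.polyval(coef, S.lags[-1])))
    return base + s_end * tau_tail


def dipole_vectors(
    positions: np.ndarray, topology: WaterTopology, cell: np.ndarray
) -> np.ndarray:
    """Unit dipole vector of each water: O toward the H-H midpoint.

    Uses minimum-image O->H displacements so molecules straddling the box
    boundary are handled correctly.
    """
    o = positions[topology.molecules[:, 0]]
    h1 = minimum_image_displacement(o, positions[topology.molecules[:, 1]], cell)
    h2 = minimum_image_displacement(o, positions[topology.molecules[:, 2]], cell)
    mu = 0.5 * (h1 + h2)
    norm = np.linalg.norm(mu, axis=1)
    if np.any(norm < 1e-8):
        bad = np.flatnonzero(norm < 1e-8)
        raise ValueError(f"degenerate water geometry for molecules {bad.tolist()}")
    return mu / norm[:, None]


def dipole_series(traj: Trajectory, topology: WaterTopology) -> np.ndarray:
    """(n_frames, n_molecules, 3) stack of unit dipole vectors."""
    return np.stack(
        [
            dipole_vectors(traj.positions[f], topology, traj.cell[f])
            for f in range(traj.n_frames)
        ]
    )


def dipole_tcf(
    traj: Trajectory,
    topology: WaterTopology,
    selection: np.ndarray | None = None,
    window: float = 16.0,
    origin_stride: int = 1,
) -> CorrelationFunction:
    """First-order Legendre dipole correlation C1(t).

    ``selection`` may be a static molecule index array or an
    ``(n_frames, n_molecules)`` boolean mask evaluated at each time origin
    (origin membership; the dipole is then tracked across the window).
    The default 16 ps window follows the multi-origin protocol.
    """
    mu = dipole_series(traj, topology)
    origin_selection = None
    if selection is not None:
        selection = np.asarray(selection)
        if selection.ndim == 1:
            if selection.size == 0:
                raise ValueError("empty selection")
            mu = mu[:, selection.astype(int)]
        else:
            origin_selection = selection.astype(bool)
    return correlate(
        mu, traj.dt, window, origin_stride=origin_stride, kernel="dot",
        origin_selection=origin_selection,
    )


def _biexp(t, a, b, tau1, tau2):
    return a * np.exp(-t / tau1) + b * np.exp(-t / tau2)


def fit_biexponential(
    C: CorrelationFunction,
    fit_start: float = 0.2,
    n_starts: int = 5,
    weighting: str = "variance",
    model_selection_ratio: float = 10.0,
    noise_floor: float = 0.05,
) -> BiExpFit:
    """Fit a*exp(-t/tau1)+b*exp(-t/tau2) to C(t) for t >= fit_start.

    ``fit_start`` (default 0.2 ps) excludes the fast librational transient.
    Multi-start nonlinear least squares on C(t) itself (not log C, which
    blows up tail noise) with positivity bounds; ``tau_reor`` is the
    amplitude-weighted mean of the two times.

    ``weighting="variance"`` weights residuals by the lag-dependent
    statistical uncertainty of a normalized TCF estimate,
    sigma(t) ~ sqrt(1 - C(t)^2): early lags are far more precise than the
    tail, whose noise is strongly correlated across lags ("none" restores
    equal weights).  Because such correlated tail noise can masquerade as a
    second relaxation mode, the nested single-exponential model is also fit
    and the second mode is kept only when it improves the weighted SSR by
    ``model_selection_ratio`` (or when its amplitude/time degenerate, in
    which case the single-exponential result is returned with b = 0).

    The fit range is truncated where C(t) first drops below ``noise_floor``
    (relative to C at fit_start): beyond that point a finite-sample TCF is
    statistical noise whose correlated wiggles bias the fit.
    """
    mask = C.lags >= fit_start
    t = C.lags[mask]
    y = C.values[mask]
    if t.size < 5:
        raise ValueError("too few points beyond fit_start for a fit")
    if noise_floor > 0 and y.size:
        below = np.flatnonzero(y < noise_floor * abs(y[0]))
        if below.size and below[0] > 10:
            t, y = t[: below[0]], y[: below[0]]
    if weighting == "variance":
        y0 = max(abs(y[0]), 1e-12)
        sig = np.sqrt(np.clip(1.0 - (y / y0) ** 2, 1e-4, None))
    elif weighting == "none":
        sig = None
    else:
        raise ValueError("weighting must be 'variance' or 'none'")

    # crude scale from the integral of the decaying part; relaxation times
    # far beyond the window are not identifiable, so tau is bounded
    tau_scale = max(float(np.trapezoid(np.clip(y, 0, None), t)) / max(y[0], 1e-12), t[1] - t[0])
    tau_max = 5.0 * t[-1]
    tau_scale = min(tau_scale, 0.5 * tau_max)

    def _ssr(res):
        return float(res @ res)

    best = None
    for ratio in np.logspace(-0.9, 0.9, n_starts):
        p0 = [
            0.5 * y[0], 0.5 * y[0],
            min(tau_scale / (1 + ratio), tau_max),
            min(tau_scale * (1 + ratio), tau_max),
        ]
        try:
            popt, _ = curve_fit(
                _biexp, t, y, p0=p0, sigma=sig,
                bounds=([0, 0, 1e-6, 1e-6], [np.inf, np.inf, tau_max, tau_max]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        res = (y - _biexp(t, *popt)) / (sig if sig is not None else 1.0)
        ssr = _ssr(res)
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        raise RuntimeError(
            "bi-exponential fit failed to converge from any start "
            f"(n={t.size} points, fit_start={fit_start} ps)"
        )
    a, b, tau1, tau2 = best[0]
    if tau1 > tau2:
        a, b, tau1, tau2 = b, a, tau2, tau1

    def _single(tt, amp, tau):
        return amp * np.exp(-tt / tau)

    try:
        popt1, _ = curve_fit(
            _single, t, y, p0=[y[0], tau_scale], sigma=sig,
            bounds=([0, 1e-6], [np.inf, tau_max]), maxfev=20000,
        )
        res1 = (y - _single(t, *popt1)) / (sig if sig is not None else 1.0)
        ssr1 = _ssr(res1)
    except (RuntimeError, ValueError):
        popt1, ssr1 = None, np.inf

    degenerate = (
        (a + b) <= 0
        or min(a, b) / (a + b) < 1e-3
        or abs(tau2 - tau1) / tau2 < 1e-3
        # a mode slower than ~the fitted range never shows its decay, so its
        # amplitude/time split (and hence tau_reor) is not identifiable
        or tau2 > 0.7 * t[-1]
    )
    if popt1 is not None and (degenerate or ssr1 <= best[1] * model_selection_ratio):
        amp, tau = popt1
        return BiExpFit(
            a=float(amp), b=0.0, tau1=float(tau), tau2=float(tau),
            tau_reor=float(tau), fit_start=float(fit_start),
            residual_rms=float(np.sqrt(np.mean((y - _single(t, *popt1)) ** 2))),
        )
    tau_reor = (a * tau1 + b * tau2) / (a + b)
    return BiExpFit(
        a=float(a), b=float(b), tau1=float(tau1), tau2=float(tau2),
        tau_reor=float(tau_reor), fit_start=float(fit_start),
        residual_rms=float(np.sqrt(np.mean((y - _biexp(t, a, b, tau1, tau2)) ** 2))),
    )


def vacf_spectrum(
    velocities: np.ndarray, dt: float, window: float, origin_stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Spectrum of the normalized VACF of a velocity series.

    ``velocities`` is (n_frames, n_atoms, 3).  The VACF is normalized to 1
    at zero lag, tapered by a one-sided half-Hann window (1 at t=0, 0 at the
    window end, so the zero-lag delta of uncorrelated motion survives), and
    the magnitude of the one-sided discrete Fourier transform is returned on
    a wavenumber grid in cm^-1.
    """
    c = correlate(np.asarray(velocities, float), dt, window, origin_stride, "dot")
    vacf = c.values / c.values[0]
    n = vacf.size
    taper = np.cos(0.5 * np.pi * np.arange(n) / (n - 1)) ** 2
    spec = np.abs(np.fft.rfft(vacf * taper))
    freq = np.fft.rfftfreq(n, d=dt)  # cycles / ps
    return freq / _C_CM_PER_PS, spec


def vdos(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    window: float = 2.0,
    origin_stride: int = 1,
    species: tuple[str, ...] = ("O", "H"),
) -> VDOSSpectrum:
    """Vibrational density of states from per-species VACFs.

    ``selection`` optionally restricts the analysis to the atoms of a set of
    molecules (e.g. the first hydration shell of a cation).  Each species'
    VACF is normalized before transforming; the total is the sum of the
    per-species spectra.  No mass weighting (plain velocity autocorrelation
    sums).
    """
    if not traj.has_velocities:
        raise ValueError("trajectory has no velocities; VDOS needs them")
    atoms_by_species: dict[str, np.ndarray] = {}
    if selection is not None:
        sel_atoms = np.unique(np.asarray(selection, dtype=int).ravel())
    else:
        sel_atoms = np.arange(traj.n_atoms)
    for sp in species:
        idx = sel_atoms[traj.elements[sel_atoms] == sp]
        if idx.size:
            atoms_by_species[sp] = idx
    if not atoms_by_species:
        raise ValueError("selection contains none of the requested species")
    intensity: dict[str, np.ndarray] = {}
    wavenumbers = None
    for sp, idx in atoms_by_species.items():
        wavenumbers, spec = vacf_spectrum(
            traj.velocities[:, idx], traj.dt, window, origin_stride
        )
        intensity[sp] = spec
    intensity["total"] = np.sum([intensity[sp] for sp in atoms_by_species], axis=0)
    return VDOSSpectrum(wavenumbers=wavenumbers, intensity=intensity)
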