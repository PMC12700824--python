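"""Correlation analysis: detrending, auto-/cross-correlation, diffusion fits
and dual-color cross-correlation (FCCS) bound fractions.

The normalized correlation function of two intensity channels is

    G(tau) = <dF_a(t) dF_b(t + tau)> / (<F_a> <F_b>),

estimated either directly (the O(n*m) definition) or with a multi-tau scheme
(16 lags, then 8 per doubling of the bin width, symmetric normalization),
the community standard for lag ranges spanning many decades.  Standard
errors come from block averaging.

Autocorrelation curves are fitted with the one-species 3D free-diffusion
model at fixed shape factor S,

    G(tau) = (1/N) (1 + tau/tau_D)^-1 (1 + tau/(S^2 tau_D))^-1/2,

whose zero-lag amplitude is the reciprocal mean occupancy.  For FCCS, the
ratio of the cross-correlation amplitude to the autocorrelation amplitude of
the *other* channel gives the fraction of the less concentrated construct in
complex; spectral bleedthrough (estimated from a green-only negative
control) is removed by linear unmixing of the covariances, and imperfect
channel overlap is compensated by the amplitude ratio measured on a covalent
green–red positive control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
import lmfit

from .exceptions import FitError, UndeterminedError, ValidationError
from .simulate import PhotonTrace

__all__ = [
    "CorrelationCurve",
    "FCSFit",
    "FCCSResult",
    "detrend",
    "correlate",
    "diffusion_model",
    "fit_diffusion",
    "diffusion_ratio",
    "bleedthrough_coefficient",
    "unmix_bleedthrough",
    "fccs_bound_fraction",
]


@dataclass
class CorrelationCurve:
    """Correlation amplitudes G(tau) with block-averaged standard errors."""

    lags: np.ndarray  # s, strictly increasing
    G: np.ndarray
    se: np.ndarray
    kind: str  # auto_g | auto_r | cross
    mean_a: float = float("nan")  # mean counts/bin of first channel
    mean_b: float = float("nan")
    bin_width: float = float("nan")

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.kind not in ("auto_g", "auto_r", "cross"):
            raise ValidationError("kind must be auto_g, auto_r or cross")
        if not (np.diff(self.lags) > 0).all() or (self.lags <= 0).any():
            raise ValidationError("lags must be positive and strictly increasing")
        if not np.isfinite(self.G).all():
            raise ValidationError("G must be finite")
        if (self.se < 0).any():
            raise ValidationError("se must be >= 0")


@dataclass
class FCSFit:
    """One-species 3D diffusion fit: occupancy, diffusion time, amplitude."""

    N: float
    tau_D: float
    S: float
    chi2_reduced: float
    G0_stderr: float = float("nan")
    tau_D_stderr: float = float("nan")

    def __post_init__(self):
        if self.N <= 0 or self.tau_D <= 0:
            raise ValidationError("N and tau_D must be > 0")

    @property
    def G0(self) -> float:
        """Zero-lag amplitude, exactly 1/N by construction."""
        return 1.0 / self.N


@dataclass
class FCCSResult:
    """Corrected FCCS amplitudes and bound fraction of the rarer construct."""

    bound_fraction: float
    G0_g: float
    G0_r: float
    G0_x: float
    bleed_coeff: float
    overlap_factor: float
    clamped: bool = False
    less_concentrated: str = "g"
    raw_fraction: float = float("nan")
    se: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.bound_fraction <= 1.0):
            raise ValidationError("bound_fraction must lie in [0, 1] after clamping")
        if not (0.0 < self.overlap_factor <= 1.0):
            raise ValidationError("overlap_factor must be in (0, 1]")


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------

def _requantize(scaled: np.ndarray) -> np.ndarray:
    """Error-diffusion rounding: integers whose running sum tracks the input.

    Preserves the total count to within one photon.
    """
    c = np.round(np.cumsum(scaled))
    return np.diff(c, prepend=0.0).astype(np.int64)


def detrend(trace: PhotonTrace, window: float = 1.0) -> PhotonTrace:
    """Suppress fluctuations slower than ``window`` (s) by local normalization.

    Each channel is rescaled by (global mean) / (moving average over the
    window) and re-quantized to integer counts preserving the total within
    0.1%.  Fluctuations faster than the window — the diffusion signal — are
    preserved.  Used before correlation when acquisitions show slow drift
    (bleaching, focus drift, cell movement).
    """
    w_bins = int(round(window / trace.bin_width))
    if window < 100 * trace.bin_width:
        raise ValidationError("window must be >= 100 bins")
    if window >= trace.duration:
        raise ValidationError("window must be shorter than the acquisition")
    out = {}
    for name in ("g", "r"):
        counts = trace.channel(name).astype(float)
        mean = counts.mean()
        if mean == 0:
            out[name] = counts.astype(np.int64)
            continue
        local = uniform_filter1d(counts, size=w_bins, mode="reflect")
        local = np.maximum(local, 1e-12)
        scaled = counts * (mean / local)
        q = _requantize(scaled)
        q[q < 0] = 0
        out[name] = q
    meta = dict(trace.metadata)
    meta["detrended_window_s"] = window
    return PhotonTrace(trace.bin_width, out["g"], out["r"], metadata=meta)


# ---------------------------------------------------------------------------
# Correlation estimators
# ---------------------------------------------------------------------------

def _corr_at_lag(a: np.ndarray, b: np.ndarray, m: int) -> float:
    """Symmetrically normalized correlation estimate at integer lag m >= 1."""
    n = a.size
    a0 = a[: n - m]
    b1 = b[m:]
    ma = a0.mean()
    mb = b1.mean()
    if ma == 0.0 or mb == 0.0:
        raise ValidationError("zero-mean channel segment: cannot normalize")
    return float(np.dot(a0, b1) / a0.size / (ma * mb) - 1.0)


def _rebin2(x: np.ndarray) -> np.ndarray:
    n = (x.size // 2) * 2
    return x[:n].reshape(-1, 2).sum(axis=1)


def _multi_tau_lags(n: int, n_casc_lags: int = 16, max_lag: int | None = None):
    """Lag schedule (lag_bins, rebin_factor) of the m=16 multi-tau scheme."""
    sched = []
    f = 1
    for m in range(1, n_casc_lags + 1):
        sched.append((m, f))
    while True:
        f *= 2
        new = [(m * f, f) for m in range(n_casc_lags // 2 + 1, n_casc_lags + 1)]
        if max_lag is not None and new[0][0] > max_lag:
            break
        if n // f < 4 * n_casc_lags:
            break
        sched.extend((lag, fac) for lag, fac in new if max_lag is None or lag <= max_lag)
    return sched


def _multitau_kernel(a: np.ndarray, b: np.ndarray, sched) -> np.ndarray:
    """Evaluate the multi-tau estimator: progressive rebinning, normalized
    per stage on the rebinned series (intensity normalization is unaffected
    by summing bins, so amplitudes remain comparable across stages)."""
    G = np.empty(len(sched))
    cur_a, cur_b = a.astype(float), b.astype(float)
    cur_f = 1
    for i, (lag, f) in enumerate(sched):
        while f > cur_f:
            cur_a = _rebin2(cur_a)
            cur_b = _rebin2(cur_b)
            cur_f *= 2
        G[i] = _corr_at_lag(cur_a, cur_b, lag // f)
    return G


def _direct_kernel(a: np.ndarray, b: np.ndarray, lag_bins) -> np.ndarray:
    return np.array([_corr_at_lag(a.astype(float), b.astype(float), int(m)) for m in lag_bins])


def correlate(
    trace: PhotonTrace,
    channel_a: str = "g",
    channel_b: str = "g",
    scheme: str = "multi_tau",
    lag_bins=None,
    n_blocks: int = 16,
) -> CorrelationCurve:
    """Auto- or cross-correlate two channels of a photon trace.

    ``scheme='multi_tau'`` uses the logarithmic m=16 correlator;
    ``scheme='direct'`` evaluates the plain O(n*m) estimator at ``lag_bins``
    (integer lags at native binning; defaults to the multi-tau schedule's
    native-resolution lags).  Standard errors come from ``n_blocks``-block
    averaging; the maximum lag is capped at a quarter block so that every
    block supports every lag.
    """
    a = trace.channel(channel_a)
    b = trace.channel(channel_b)
    n = a.size
    if a.mean() == 0 or b.mean() == 0:
        raise ValidationError("zero-mean channel: cannot normalize correlation")
    max_lag = n // (4 * n_blocks)

    if scheme == "multi_tau":
        sched = _multi_tau_lags(n, max_lag=max_lag)
        kernel = lambda x, y: _multitau_kernel(x, y, sched)
        lags_b = np.array([lag for lag, _ in sched])
    elif scheme == "direct":
        if lag_bins is None:
            lag_bins = [lag for lag, _ in _multi_tau_lags(n, max_lag=max_lag)]
        lags_b = np.asarray(lag_bins, dtype=int)
        if (lags_b < 1).any() or not (np.diff(lags_b) > 0).all():
            raise ValidationError("lag_bins must be increasing positive integers")
        kernel = lambda x, y: _direct_kernel(x, y, lags_b)
    else:
        raise ValidationError("scheme must be 'multi_tau' or 'direct'")

    G = kernel(a, b)

    # block-averaged standard errors
    blk = n // n_blocks
    block_G = []
    for i in range(n_blocks):
        sl = slice(i * blk, (i + 1) * blk)
        if a[sl].mean() == 0 or b[sl].mean() == 0:
            continue
        try:
            block_G.append(kernel(a[sl], b[sl]))
        except ValidationError:
            continue
    if len(block_G) >= 2:
        se = np.std(np.vstack(block_G), axis=0, ddof=1) / math.sqrt(len(block_G))
    else:
        se = np.zeros_like(G)

    if channel_a == channel_b:
        kind = "auto_g" if channel_a == "g" else "auto_r"
    else:
        kind = "cross"
    return CorrelationCurve(
        lags=lags_b * trace.bin_width,
        G=G,
        se=se,
        kind=kind,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        bin_width=trace.bin_width,
    )


# ---------------------------------------------------------------------------
# Diffusion model fitting
# ---------------------------------------------------------------------------

def diffusion_model(tau, G0: float, tau_D: float, S: float = 6.0):
    """One-species 3D-Gaussian free-diffusion correlation model."""
    tau = np.asarray(tau, dtype=float)
    return G0 / (1.0 + tau / tau_D) / np.sqrt(1.0 + tau / (S**2 * tau_D))


def fit_diffusion(
    curve: CorrelationCurve,
    S: float = 6.0,
    fix_tau_D: float | None = None,
    allow_negative_G0: bool = False,
    use_se_weights: bool = False,
) -> FCSFit:
    """Least-squares fit of the one-species diffusion model.

    The shape factor is fixed (default 6, not fitted).  The default is an
    unweighted fit over the (log-spaced) lags: block-averaged errors from 16
    blocks are themselves noisy and correlate with the per-lag fluctuations,
    and 1/se^2 weighting then biases amplitude and diffusion time downward
    at low occupancy.  Pass ``use_se_weights=True`` to weight by 1/se^2
    anyway (e.g. for externally supplied, well-averaged error bars).  Use
    ``fix_tau_D`` to fit only the amplitude (e.g. cross-correlation curves
    whose amplitude may be near zero), optionally allowing a negative G0 so
    that a true zero amplitude is an interior point of the fit.
    """
    if curve.lags.size < 20 or curve.lags[-1] / curve.lags[0] < 1e3:
        warnings.warn(
            ">= 20 lags spanning >= 3 decades recommended for a stable diffusion fit",
            stacklevel=2,
        )
    tau = curve.lags
    G = curve.G
    se = np.where(curve.se > 0, curve.se, np.nan)
    if not use_se_weights or np.isnan(se).all():
        weights = np.ones_like(G)
    else:
        floor = np.nanmedian(se) * 1e-3
        weights = 1.0 / np.where(np.isnan(se), np.nanmedian(se), np.maximum(se, floor))

    G0_init = max(G[0], 1e-6) if not allow_negative_G0 else G[0]
    half = np.nonzero(G < G0_init / 2.0)[0]
    tau_init = tau[half[0]] if half.size else tau[tau.size // 2]

    params = lmfit.Parameters()
    if allow_negative_G0:
        params.add("G0", value=G0_init)
    else:
        params.add("G0", value=G0_init, min=1e-12)
    if fix_tau_D is not None:
        params.add("tau_D", value=float(fix_tau_D), vary=False)
    else:
        params.add("tau_D", value=float(tau_init), min=tau[0] / 100.0, max=tau[-1] * 100.0)

    def residual(p):
        return (G - diffusion_model(tau, p["G0"].value, p["tau_D"].value, S)) * weights

    res = lmfit.minimize(residual, params, method="leastsq", xtol=1e-14, ftol=1e-14)
    if not (res.success or "tolerance" in (res.message or "").lower()):
        raise FitError(
            f"diffusion fit did not converge: {res.message}",
            last_params={k: v.value for k, v in res.params.items()},
        )
    G0 = res.params["G0"].value
    tau_D = res.params["tau_D"].value
    if not (tau[0] <= tau_D <= tau[-1]):
        warnings.warn("fitted tau_D lies outside the lag range (extrapolation)", stacklevel=2)
    if G0 <= 0:
        # amplitude consistent with zero: report a tiny positive occupancy bound
        G0_eff = 1e-12
    else:
        G0_eff = G0
    nfree = max(G.size - res.nvarys, 1)
    fit = FCSFit(
        N=1.0 / G0_eff,
        tau_D=tau_D,
        S=S,
        chi2_reduced=float(np.sum(res.residual**2)) / nfree,
        G0_stderr=res.params["G0"].stderr or float("nan"),
        tau_D_stderr=(res.params["tau_D"].stderr or float("nan")) if fix_tau_D is None else 0.0,
    )
    # keep the signed amplitude accessible for near-zero cross curves
    fit.__dict__["G0_signed"] = G0
    return fit


def diffusion_ratio(fit_small: FCSFit, fit_large: FCSFit) -> float:
    """D(smaller species) / D(larger species) from the two diffusion times.

    Equal to tau_D(large)/tau_D(small) in the same detection volume; expected
    >= 1 when the inputs are size-ordered (warns otherwise).
    """
    ratio = fit_large.tau_D / fit_small.tau_D
    if ratio < 1.0:
        warnings.warn("diffusion ratio < 1: inputs may not be size-ordered", stacklevel=2)
    return ratio


# ---------------------------------------------------------------------------
# FCCS: bleedthrough and bound fraction
# ---------------------------------------------------------------------------

def bleedthrough_coefficient(
    negative_control: PhotonTrace,
    background_g: float = 0.0,
    background_r: float = 0.0,
) -> float:
    """Green-to-red bleedthrough from a green-only negative control.

    coefficient = <F_r> / <F_g> after background subtraction (backgrounds in
    counts/s).  Raises :class:`UndeterminedError` when the green signal does
    not rise above background.
    """
    T = negative_control.bin_width
    mg = negative_control.counts_g.mean() - background_g * T
    mr = negative_control.counts_r.mean() - background_r * T
    n = len(negative_control)
    noise = 3.0 * math.sqrt(max(negative_control.counts_g.mean(), 1e-12) / n)
    if mg <= noise:
        raise UndeterminedError("green signal at background level; bleedthrough undetermined")
    return float(mr / mg)


def unmix_bleedthrough(
    G_g: CorrelationCurve,
    G_r: CorrelationCurve,
    G_x: CorrelationCurve,
    bleed: float,
):
    """Remove green->red bleedthrough from red-auto and cross curves.

    With measured intensities F_g = G and F_r = R + beta*G the covariances
    unmix linearly:

        cov_GR = cov_gx - beta cov_gg
        cov_RR = cov_rr - 2 beta cov_gx + beta^2 cov_gg

    and the true red mean is <F_r> - beta <F_g>.  Normalized curves are
    rebuilt from the unmixed covariances.  The green autocorrelation is
    unaffected.  Curves must share a common lag grid and carry mean counts.
    """
    if not (0.0 <= bleed < 1.0):
        raise ValidationError("bleed must be in [0, 1)")
    if bleed == 0.0:
        return G_g, G_r, G_x
    for c in (G_r, G_x):
        if c.lags.shape != G_g.lags.shape or not np.allclose(c.lags, G_g.lags):
            raise ValidationError("curves must share a common lag grid")
    mg = G_g.mean_a
    mr = G_r.mean_a
    mx_g, mx_r = G_x.mean_a, G_x.mean_b
    if any(not np.isfinite(v) for v in (mg, mr, mx_g, mx_r)):
        raise ValidationError("curves must carry mean intensities for unmixing")
    cov_gg = G_g.G * mg * mg
    cov_rr = G_r.G * mr * mr
    cov_gx = G_x.G * mx_g * mx_r
    mr_true = mr - bleed * mg
    if mr_true <= 0:
        raise UndeterminedError("red mean does not exceed bleedthrough level")
    cov_GR = cov_gx - bleed * cov_gg
    cov_RR = cov_rr - 2.0 * bleed * cov_gx + bleed**2 * cov_gg
    G_r_c = CorrelationCurve(
        lags=G_r.lags, G=cov_RR / mr_true**2,
        se=G_r.se * (mr / mr_true) ** 2, kind="auto_r",
        mean_a=mr_true, mean_b=mr_true, bin_width=G_r.bin_width,
    )
    G_x_c = CorrelationCurve(
        lags=G_x.lags, G=cov_GR / (mg * mr_true),
        se=G_x.se * (mr / mr_true), kind="cross",
        mean_a=mg, mean_b=mr_true, bin_width=G_x.bin_width,
    )
    return G_g, G_r_c, G_x_c


def fccs_bound_fraction(
    G_g: CorrelationCurve,
    G_r: CorrelationCurve,
    G_x: CorrelationCurve,
    bleed: float = 0.0,
    positive_control_ratio: float = 1.0,
    S: float = 6.0,
) -> FCCSResult:
    """Fraction of the less concentrated construct in complex.

    Amplitudes are taken from one-species diffusion fits of the (bleedthrough-
    corrected) auto- and cross-correlation curves; the cross amplitude is
    fitted with its diffusion time fixed at the autocorrelation average so a
    zero amplitude remains well-posed.  The less concentrated channel is the
    one with the larger autocorrelation amplitude (G0 = 1/N; ties go to green
    by convention).  Then

        raw = G0_x / G0_(other channel)   (= N_complex / N_less)
        bound_fraction = clamp(raw / overlap_factor, 0, 1)

    where ``overlap_factor`` (the ``positive_control_ratio``) is the maximal
    amplitude ratio achievable on a covalent green–red fusion, compensating
    imperfect overlap of the two detection volumes.
    """
    if positive_control_ratio <= 0 or positive_control_ratio > 1.0:
        raise ValidationError("positive_control_ratio must be in (0, 1]")
    G_g, G_r, G_x = unmix_bleedthrough(G_g, G_r, G_x, bleed)
    fit_g = fit_diffusion(G_g, S=S)
    fit_r = fit_diffusion(G_r, S=S)
    tau_x = 0.5 * (fit_g.tau_D + fit_r.tau_D)
    fit_x = fit_diffusion(G_x, S=S, fix_tau_D=tau_x, allow_negative_G0=True)
    g0_g, g0_r = fit_g.G0, fit_r.G0
    g0_x = fit_x.__dict__.get("G0_signed", fit_x.G0)

    less = "g" if g0_g >= g0_r else "r"
    other_g0 = g0_r if less == "g" else g0_g
    raw = g0_x / other_g0
    corrected = raw / positive_control_ratio
    clamped = not (0.0 <= corrected <= 1.0)
    bound = min(max(corrected, 0.0), 1.0)
    se = float("nan")
    if np.isfinite(fit_x.G0_stderr):
        se = abs(fit_x.G0_stderr / other_g0 / positive_control_ratio)
    return FCCSResult(
        bound_fraction=bound,
        G0_g=g0_g,
        G0_r=g0_r,
        G0_x=g0_x,
        bleed_coeff=bleed,
        overlap_factor=positive_control_ratio,
        clamped=clamped,
        less_concentrated=less,
        raw_fraction=raw,
        se=se,
    )
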