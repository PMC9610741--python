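"""AFM height-field analysis: globule detection and altitude deconvolution.

The pipeline mirrors how particle heights on a supported bilayer are
measured: estimate the bilayer background plane, detect individual
globules as local maxima above a threshold, take each globule's peak
altitude over the background, and decompose the pooled altitude sample
into K Gaussian populations.

The mixture is fitted by expectation-maximization on the raw altitude
samples rather than least squares on a binned histogram — the result is
free of bin-width sensitivity; a histogram least-squares backend is
provided for cross-checking.  K is always chosen by the caller; an
information-criterion sweep is available but never applied automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import FitError, UsageError
from .structio import HeightField


@dataclass
class ParticleMeasurement:
    """One detected globule."""

    position: np.ndarray  # (x, y) nm
    peak_altitude_nm: float
    footprint_px: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)
        if self.footprint_px < 1:
            raise UsageError("footprint_px must be >= 1")


@dataclass
class MixtureFit:
    """A K-component 1-D Gaussian mixture fit (means sorted ascending)."""

    K: int
    means_nm: np.ndarray
    sds_nm: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    converged: bool
    n_samples: int

    def __post_init__(self) -> None:
        self.means_nm = np.asarray(self.means_nm, dtype=float).reshape(-1)
        self.sds_nm = np.asarray(self.sds_nm, dtype=float).reshape(-1)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if not (len(self.means_nm) == len(self.sds_nm) == len(self.weights) == self.K):
            raise FitError("component vectors must all have length K")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-6:
            raise FitError("weights must be non-negative and sum to 1")
        if np.any(self.sds_nm <= 0):
            raise FitError("component sds must be positive")
        if np.any(np.diff(self.means_nm) < 0):
            raise FitError("means must be sorted ascending")


def background_plane(field: HeightField, bin_nm: float = 0.05, refine_nm: float = 0.1) -> float:
    """Robust bilayer reference height: the densest ``bin_nm`` histogram bin,
    refined by the median of all pixels within ``refine_nm`` of it."""
    h = field.heights.ravel()
    lo, hi = float(h.min()), float(h.max())
    if hi - lo < bin_nm:
        return float(np.median(h))
    edges = np.arange(lo, hi + bin_nm, bin_nm)
    counts, edges = np.histogram(h, bins=edges)
    mode_center = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    near = h[np.abs(h - mode_center) <= refine_nm]
    return float(np.median(near)) if len(near) else float(mode_center)


def detect_particles(
    field: HeightField,
    min_altitude_nm: float = 0.5,
    min_separation_nm: float = 4.0,
) -> list[ParticleMeasurement]:
    """Globules as local maxima above background + ``min_altitude_nm``.

    Maxima closer than ``min_separation_nm`` collapse to the taller peak.
    Footprints are the connected pixel regions above the threshold.
    """
    if not min_altitude_nm > 0:
        raise UsageError("min_altitude_nm must be > 0")
    from skimage.feature import peak_local_max
    from skimage.measure import label

    bg = background_plane(field)
    threshold = bg + min_altitude_nm
    mask = field.heights > threshold
    if not mask.any():
        return []
    labels = label(mask, connectivity=2)
    min_dist_px = max(1, int(np.ceil(min_separation_nm / field.pixel_size)))
    peaks = peak_local_max(
        field.heights,
        min_distance=min_dist_px,
        threshold_abs=threshold,
        exclude_border=False,
    )
    sizes = np.bincount(labels.ravel())
    out = []
    for row, col in peaks:
        region = labels[row, col]
        x = field.origin[0] + (col + 0.5) * field.pixel_size
        y = field.origin[1] + (row + 0.5) * field.pixel_size
        out.append(
            ParticleMeasurement(
                position=np.array([x, y]),
                peak_altitude_nm=float(field.heights[row, col] - bg),
                footprint_px=int(sizes[region]) if region > 0 else 1,
            )
        )
    out.sort(key=lambda m: (m.position[1], m.position[0]))
    return out


def _em_once(x: np.ndarray, K: int, rng: np.random.Generator,
             max_iter: int, tol: float) -> MixtureFit:
    n = len(x)
    spread = float(np.std(x))
    if spread == 0:
        raise FitError("all samples identical; mixture fit is degenerate")
    # quantile init, perturbed
    means = np.quantile(x, (np.arange(K) + 0.5) / K) + rng.normal(0.0, 0.1 * spread, K)
    sds = np.full(K, spread)
    weights = np.full(K, 1.0 / K)
    floor = 1e-6 * spread

    prev_ll = -np.inf
    converged = False
    ll = prev_ll
    for _ in range(max_iter):
        log_pdf = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :])
            - 0.5 * np.log(2.0 * np.pi)
            + np.log(weights[None, :])
        )
        norm = logsumexp(log_pdf, axis=1)
        ll = float(np.sum(norm))
        # EM guarantees monotone likelihood; check it every iteration
        if ll < prev_ll - 1e-6 * (1.0 + abs(prev_ll)):
            raise FitError("log-likelihood decreased during EM")
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        resp = np.exp(log_pdf - norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise FitError("empty component during EM")
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < floor):
            raise FitError("degenerate component (sd collapsed)")
    order = np.argsort(means)
    return MixtureFit(
        K=K,
        means_nm=means[order],
        sds_nm=sds[order],
        weights=weights[order] / weights.sum(),
        log_likelihood=ll,
        converged=converged,
        n_samples=n,
    )


def fit_gaussian_mixture(
    samples,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """Maximum-likelihood K-component 1-D Gaussian mixture via EM.

    Best of ``n_restarts`` seeded initializations (quantile means, perturbed).
    Convergence: log-likelihood gain below ``tol`` over an iteration.
    Restarts that collapse a component are discarded; if all do, a
    :class:`FitError` is raised.
    """
    x = np.asarray(samples, dtype=float).reshape(-1)
    if K < 1:
        raise UsageError(f"K must be >= 1, got {K}")
    if len(x) < 3 * K:
        raise UsageError(f"need at least {3 * K} samples for K={K}, got {len(x)}")
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=max(n_restarts, 1))
    best: MixtureFit | None = None
    for s in seeds:
        try:
            fit = _em_once(x, K, np.random.default_rng(int(s)), max_iter, tol)
        except FitError:
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise FitError(f"all {n_restarts} EM restarts were degenerate")
    return best


def fit_gaussian_sum_histogram(
    samples,
    K: int,
    bin_nm: float = 0.05,
    seed: int = 0,
) -> MixtureFit:
    """Alternative backend: least-squares fit of a sum of K Gaussians to the
    binned altitude histogram (density scale)."""
    from scipy.optimize import curve_fit

    x = np.asarray(samples, dtype=float).reshape(-1)
    if len(x) < 3 * K:
        raise UsageError(f"need at least {3 * K} samples for K={K}")
    edges = np.arange(x.min() - bin_nm, x.max() + 2 * bin_nm, bin_nm)
    density, edges = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(t, *params):
        out = np.zeros_like(t)
        for k in range(K):
            a, m, s = params[3 * k: 3 * k + 3]
            out = out + a * np.exp(-0.5 * ((t - m) / s) ** 2)
        return out

    spread = float(np.std(x))
    q = np.quantile(x, (np.arange(K) + 0.5) / K)
    p0 = []
    for k in range(K):
        p0 += [1.0 / (K * spread * np.sqrt(2 * np.pi)), float(q[k]), spread / K + 0.01]
    try:
        popt, _ = curve_fit(model, centers, density, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"histogram fit failed: {exc}") from exc
    amps = np.abs(popt[0::3])
    means = popt[1::3]
    sds = np.abs(popt[2::3])
    if np.any(sds <= 0):
        raise FitError("histogram fit produced a degenerate component")
    areas = amps * sds * np.sqrt(2 * np.pi)
    weights = areas / areas.sum()
    order = np.argsort(means)
    resid = density - model(centers, *popt)
    return MixtureFit(
        K=K,
        means_nm=means[order],
        sds_nm=sds[order],
        weights=weights[order],
        log_likelihood=-float(np.sum(resid**2)),  # not a true likelihood
        converged=True,
        n_samples=len(x),
    )


def mixture_k_sweep(samples, k_range=range(1, 6), seed: int = 0, n_restarts: int = 5):
    """BIC for each candidate K (advisory only; K is never auto-selected)."""
    x = np.asarray(samples, dtype=float).reshape(-1)
    out = {}
    for k in k_range:
        if len(x) < 3 * k:
            continue
        try:
            fit = fit_gaussian_mixture(x, k, n_restarts=n_restarts, seed=seed)
        except FitError:
            continue
        n_params = 3 * k - 1
        bic = n_params * np.log(len(x)) - 2.0 * fit.log_likelihood
        out[k] = (fit, float(bic))
    return out


def analyze_field(
    field: HeightField,
    K: int = 3,
    min_altitude_nm: float = 0.5,
    min_separation_nm: float = 4.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[list[ParticleMeasurement], MixtureFit | None]:
    """Detection followed by mixture deconvolution on one field.

    When fewer than ``3 * K`` globules are found the fit is skipped with a
    warning and ``None`` is returned in its place.
    """
    return analyze_fields([field], K, min_altitude_nm, min_separation_nm, n_restarts, seed)


def analyze_fields(
    fields,
    K: int = 3,
    min_altitude_nm: float = 0.5,
    min_separation_nm: float = 4.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[list[ParticleMeasurement], MixtureFit | None]:
    """Pooled detection + mixture fit over a batch of fields of view."""
    measurements: list[ParticleMeasurement] = []
    for f in fields:
        measurements.extend(detect_particles(f, min_altitude_nm, min_separation_nm))
    if len(measurements) < 3 * K:
        warnings.warn(
            f"only {len(measurements)} particles detected; need {3 * K} for K={K}; "
            "skipping mixture fit"
        )
        return measurements, None
    altitudes = np.array([m.peak_altitude_nm for m in measurements])
    fit = fit_gaussian_mixture(altitudes, K, n_restarts=n_restarts, seed=seed)
    return measurements, fit
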