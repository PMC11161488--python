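"""Grid-based hidden Markov geolocation of archival-tagged fish.

The latent state is the daily grid cell occupied by the fish. Movement
between days is an isotropic Gaussian diffusion kernel over water cells
(per-axis variance 2*D*dt), optionally switched between a low- and a
high-activity diffusion coefficient by a two-state activity HMM decoded
from the depth series. Observations per day combine a bathymetry
constraint (the fish cannot dive deeper than the sea floor), a
temperature match against the two-layer reference field, and, for
acoustic tags, a detection kernel around the detecting stations. The
daily posteriors come from scaled forward-backward smoothing; the
reported track is the jointly most probable sequence (Viterbi), and its
per-day distance to the posterior-mean and posterior-mode tracks grades
track reliability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from datetime import date as Date
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .geo import haversine_km
from .preprocess import CleanSeries
from .types import DailyObservation, DetectionSet, GriddedField

log = logging.getLogger("basstrack.geolocate")

__all__ = [
    "HmmConfig",
    "ActivityStates",
    "WaterGrid",
    "PosteriorTrack",
    "fit_activity_states",
    "movement_kernel",
    "depth_likelihood",
    "temperature_likelihood",
    "detection_likelihood",
    "forward_backward",
    "viterbi",
    "mean_and_modal_tracks",
    "estimate_D",
    "validate_track",
]


@dataclass(frozen=True)
class HmmConfig:
    """Observation and movement scales of the geolocation model.

    sigma_temp: temperature observation sd (°C); sigma_bathy: tolerance
    (m) for an observed max depth exceeding the cell bathymetry;
    sigma_det_m: detection kernel scale (m), the 50% daily detection
    range; d_range: search range for the diffusion coefficient
    (km^2/day).
    """

    sigma_temp: float = 0.5
    sigma_bathy: float = 4.0
    sigma_det_m: float = 566.0
    d_range: tuple[float, float] = (1.0, 100.0)
    switching: bool = True
    use_terminal_anchor: bool = False
    max_cells: int = 20000

    def __post_init__(self) -> None:
        if min(self.sigma_temp, self.sigma_bathy, self.sigma_det_m) <= 0:
            raise ValueError("all observation scales must be positive")
        lo, hi = self.d_range
        if not (0 < lo < hi):
            raise ValueError("d_range must be positive and ordered")


class WaterGrid:
    """Flattened water-cell view of a gridded field, with pairwise
    great-circle distances cached for kernel construction."""

    def __init__(self, field: GriddedField, max_cells: int = 20000) -> None:
        self.field = field
        ii, jj = np.where(field.water_mask)
        if len(ii) == 0:
            raise ValueError("field has no water cells")
        if len(ii) > max_cells:
            raise ValueError(f"{len(ii)} water cells exceed the limit {max_cells}")
        self.ii, self.jj = ii, jj
        self.cell_lats = field.lats[ii]
        self.cell_lons = field.lons[jj]
        self.bathy = field.bathymetry[ii, jj]
        self.n = len(ii)
        self.distances = haversine_km(
            self.cell_lats[:, None],
            self.cell_lons[:, None],
            self.cell_lats[None, :],
            self.cell_lons[None, :],
        )
        mid = math.radians(float(np.mean(field.lats)))
        self.diag_km = math.hypot(
            field.lat_spacing * 111.19, field.lon_spacing * 111.19 * math.cos(mid)
        )

    def nearest_cell(self, lat: float, lon: float) -> int:
        return int(np.argmin((self.cell_lats - lat) ** 2 + (self.cell_lons - lon) ** 2))

    def point_mass(self, lat: float, lon: float) -> np.ndarray:
        p = np.zeros(self.n)
        p[self.nearest_cell(lat, lon)] = 1.0
        return p


@dataclass
class ActivityStates:
    """Daily low/high activity decoding of the depth series."""

    states: np.ndarray  # 0 = low, 1 = high, aligned with the daily records
    means: np.ndarray  # state means of log(1 + activity index)
    sds: np.ndarray
    transmat: np.ndarray
    converged: bool
    separation: float  # |mu_high - mu_low| in pooled-sd units


@dataclass
class PosteriorTrack:
    """Daily posteriors with their track summaries and reliability tier."""

    tag_id: str
    dates: list[Date]
    grid: WaterGrid
    posteriors: np.ndarray  # (T, n_cells), each row sums to 1
    viterbi_track: np.ndarray  # (T, 2) lat/lon
    mean_track: np.ndarray
    modal_track: np.ndarray
    log_likelihood: float
    d_fit: tuple[float, float]  # (d_low, d_high); equal when not switching
    switching: bool
    viterbi_vs_mean_km: np.ndarray
    viterbi_vs_mode_km: np.ndarray
    reliability: str = "unreliable"
    warnings: list[str] = dc_field(default_factory=list)

    @property
    def daily_error_km(self) -> np.ndarray:
        return np.maximum(self.viterbi_vs_mean_km, self.viterbi_vs_mode_km)


# --------------------------------------------------------------------------
# activity states
# --------------------------------------------------------------------------

def fit_activity_states(
    daily: Sequence[DailyObservation],
    min_days: int = 30,
    min_separation: float = 1.0,
    random_state: int = 0,
) -> ActivityStates:
    """Two-state Gaussian HMM on log(1 + daily activity index), fitted by
    EM (<= 500 iterations, tol 1e-6) and decoded by Viterbi. The state
    with the larger mean is "high". The fit is flagged non-converged when
    EM fails or the state means are separated by less than
    ``min_separation`` pooled standard deviations — an automated stand-in
    for a visual reliability screen — in which case behavioural switching
    is disabled downstream."""
    from hmmlearn.hmm import GaussianHMM

    act = np.array([d.activity_index for d in daily], dtype=float)
    defined = np.array([d.activity_defined for d in daily], dtype=bool)
    x = np.log1p(np.clip(act[defined], 0.0, None))
    fallback = ActivityStates(
        states=np.zeros(len(daily), dtype=int),
        means=np.array([x.mean() if len(x) else 0.0] * 2),
        sds=np.array([x.std() if len(x) else 0.0] * 2),
        transmat=np.eye(2),
        converged=False,
        separation=0.0,
    )
    if defined.sum() < min_days or np.ptp(x) < 1e-9:
        return fallback

    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=500,
        tol=1e-6,
        random_state=random_state,
        init_params="sc",
    )
    model.means_ = np.quantile(x, [0.25, 0.75]).reshape(2, 1)
    model.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
    try:
        model.fit(x.reshape(-1, 1))
        decoded = model.predict(x.reshape(-1, 1))
    except Exception as exc:  # EM failure on degenerate input
        log.warning("activity HMM failed: %s", exc)
        return fallback

    means = model.means_.ravel()
    sds = np.sqrt(model.covars_.ravel())
    order = np.argsort(means)  # low first
    means, sds = means[order], sds[order]
    remap = np.empty(2, dtype=int)
    remap[order] = [0, 1]
    decoded = remap[decoded]
    transmat = model.transmat_[np.ix_(order, order)]
    pooled = math.sqrt(float(np.mean(sds**2))) or 1e-12
    separation = float(abs(means[1] - means[0]) / pooled)
    converged = bool(model.monitor_.converged) and separation >= min_separation

    states = np.zeros(len(daily), dtype=int)
    states[defined] = decoded
    # undefined-activity days inherit the previous defined state
    last = 0
    for k in range(len(daily)):
        if defined[k]:
            last = states[k]
        else:
            states[k] = last
    return ActivityStates(
        states=states,
        means=means,
        sds=sds,
        transmat=transmat,
        converged=converged,
        separation=separation,
    )


# --------------------------------------------------------------------------
# movement kernel
# --------------------------------------------------------------------------

def movement_kernel(
    d_coef: float, grid: WaterGrid, dt: float = 1.0
) -> sparse.csr_matrix:
    """Row-stochastic diffusion transition operator over water cells.

    Weight from cell i to cell j is exp(-d_ij^2 / (4 D dt)) with d the
    great-circle distance, truncated beyond 4*sqrt(2 D dt) for sparsity;
    land is excluded by construction. When the kernel support is smaller
    than one grid cell the operator degrades to the identity."""
    if d_coef <= 0:
        raise ValueError("diffusion coefficient must be positive")
    radius = 4.0 * math.sqrt(2.0 * d_coef * dt)
    if radius < grid.diag_km / 2.0:
        log.warning(
            "kernel support %.2f km below one cell (%.2f km); using identity",
            radius,
            grid.diag_km,
        )
        return sparse.identity(grid.n, format="csr")
    d2 = grid.distances
    mask = d2 <= radius
    w = np.where(mask, np.exp(-(d2**2) / (4.0 * d_coef * dt)), 0.0)
    w /= w.sum(axis=1, keepdims=True)
    return sparse.csr_matrix(w)


def _log_dense(kernel: sparse.csr_matrix) -> np.ndarray:
    dense = kernel.toarray()
    with np.errstate(divide="ignore"):
        return np.log(dense)


# --------------------------------------------------------------------------
# observation likelihoods
# --------------------------------------------------------------------------

def depth_likelihood(
    obs: DailyObservation, grid: WaterGrid, sigma_bathy: float = 4.0
) -> np.ndarray:
    """Bathymetry constraint: cells at least as deep as the day's maximum
    depth score 1; shallower cells decay as a Gaussian in the depth
    excess."""
    max_depth = max(obs.max_depth, 0.0)
    short = np.clip(max_depth - grid.bathy, 0.0, None)
    return np.exp(-(short**2) / (2.0 * sigma_bathy**2))


def temperature_likelihood(
    obs: DailyObservation,
    grid: WaterGrid,
    sigma_temp: float = 0.5,
) -> np.ndarray:
    """Gaussian match of the day's mean temperature against the reference
    temperature at the fish's median depth fraction, interpolated between
    the surface and bottom layers per cell. Cooling-water days carry no
    temperature information and return a uniform likelihood."""
    if obs.cooling_water:
        return np.ones(grid.n)
    k = grid.field.day_index(obs.date)
    frac = np.clip(max(obs.med_depth, 0.0) / grid.bathy, 0.0, 1.0)
    surf = grid.field.temp_surface[k][grid.ii, grid.jj]
    bot = grid.field.temp_bottom[k][grid.ii, grid.jj]
    ref = surf + (bot - surf) * frac
    return np.exp(-((obs.mean_temp - ref) ** 2) / (2.0 * sigma_temp**2))


def detection_likelihood(
    day: Date,
    detections: pd.DataFrame,
    stations: pd.DataFrame,
    grid: WaterGrid,
    sigma_det_m: float = 566.0,
    floor: float = 1e-6,
) -> np.ndarray:
    """Positive-information detection kernel: on days with detections the
    likelihood is, per cell, the maximum over detecting stations of
    exp(-ln2 (d/sigma_d)^2) floored at ``floor``; days without detections
    are uninformative (uniform)."""
    if len(detections) == 0:
        return np.ones(grid.n)
    day_det = detections[pd.to_datetime(detections["timestamp"]).dt.date == day]
    if len(day_det) == 0:
        return np.ones(grid.n)
    st = stations.set_index("station_id")
    lik = np.zeros(grid.n)
    sigma_km = sigma_det_m / 1000.0
    for sid in day_det["station_id"].unique():
        s = st.loc[sid]
        d = haversine_km(grid.cell_lats, grid.cell_lons, float(s["lat"]), float(s["lon"]))
        lik = np.maximum(lik, np.exp(-math.log(2.0) * (d / sigma_km) ** 2))
    return np.maximum(lik, floor)


def combine_likelihoods(*terms: np.ndarray) -> np.ndarray:
    """Product of independent per-cell likelihood terms, normalised to sum
    1 (which makes the model log-likelihood invariant to uniform
    rescaling of any day's likelihood). An all-zero product is relaxed to
    uniform."""
    out = np.ones_like(terms[0])
    for t in terms:
        out = out * t
    s = out.sum()
    if s <= 0.0 or not np.isfinite(s):
        return np.full_like(out, 1.0 / len(out))
    return out / s


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _kernel_for_day(kernels, t: int):
    if isinstance(kernels, (list, tuple)):
        return kernels[t]
    return kernels


def forward_backward(
    likelihoods: np.ndarray,
    kernels,
    prior: np.ndarray,
    warnings: Optional[list[str]] = None,
) -> tuple[np.ndarray, float]:
    """Scaled forward filtering and backward smoothing.

    ``likelihoods`` is (T, n); ``kernels`` is a single transition operator
    or a per-transition sequence of length T-1; ``prior`` is the day-1
    prior (e.g. a point mass at the release cell). Returns the smoothed
    per-day posteriors (each summing to 1) and the log-likelihood. Days
    whose predicted mass vanishes everywhere are relaxed to uniform and
    recorded as warnings rather than collapsing the model."""
    T, n = likelihoods.shape
    alphas = np.empty((T, n))
    logc = 0.0
    a = prior * likelihoods[0]
    c = a.sum()
    if c <= 0:
        if warnings is not None:
            warnings.append("day 0: zero likelihood mass, relaxed to uniform")
        a = np.full(n, 1.0 / n)
        c = 1.0
    alphas[0] = a / c
    logc += math.log(c)
    for t in range(1, T):
        K = _kernel_for_day(kernels, t - 1)
        pred = K.T @ alphas[t - 1]
        a = pred * likelihoods[t]
        c = a.sum()
        if c <= 0:
            if warnings is not None:
                warnings.append(f"day {t}: zero likelihood mass, relaxed to uniform")
            a = np.full(n, 1.0 / n)
            c = 1.0
        alphas[t] = a / c
        logc += math.log(c)

    post = np.empty((T, n))
    b = np.ones(n)
    post[T - 1] = alphas[T - 1]
    for t in range(T - 2, -1, -1):
        K = _kernel_for_day(kernels, t)
        b = K @ (likelihoods[t + 1] * b)
        s = b.sum()
        if s > 0:
            b = b / s
        p = alphas[t] * b
        ps = p.sum()
        post[t] = p / ps if ps > 0 else np.full(n, 1.0 / n)
    return post, logc


def viterbi(
    likelihoods: np.ndarray,
    kernels,
    prior: np.ndarray,
) -> np.ndarray:
    """Jointly most probable cell sequence (ties toward the lower cell
    index). Returns the per-day cell indices."""
    T, n = likelihoods.shape
    with np.errstate(divide="ignore"):
        loglik = np.log(likelihoods)
        logprior = np.log(prior)
    log_cache: dict[int, np.ndarray] = {}

    def logK(K) -> np.ndarray:
        key = id(K)
        if key not in log_cache:
            log_cache[key] = _log_dense(K)
        return log_cache[key]

    delta = logprior + loglik[0]
    if np.all(np.isneginf(delta)):
        delta = loglik[0].copy()
    psi = np.empty((T - 1, n), dtype=np.int32) if T > 1 else None
    for t in range(1, T):
        M = delta[:, None] + logK(_kernel_for_day(kernels, t - 1))
        best = np.argmax(M, axis=0)  # first (lowest) index on ties
        psi[t - 1] = best
        delta = M[best, np.arange(n)] + loglik[t]
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t][path[t + 1]]
    return path


def mean_and_modal_tracks(
    posteriors: np.ndarray, grid: WaterGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-weighted mean positions and per-day argmax cells."""
    mean = np.column_stack(
        [posteriors @ grid.cell_lats, posteriors @ grid.cell_lons]
    )
    modal_idx = np.argmax(posteriors, axis=1)
    modal = np.column_stack([grid.cell_lats[modal_idx], grid.cell_lons[modal_idx]])
    return mean, modal


def validate_track(track: PosteriorTrack) -> str:
    """Reliability tier from the per-day max of the Viterbi-vs-mean and
    Viterbi-vs-mode distances: reliable when the median error is below
    50 km and the maximum below 120 km; still usable for temporal
    summaries up to a 240 km maximum; unreliable beyond."""
    err = track.daily_error_km
    med, mx = float(np.median(err)), float(np.max(err))
    if med < 50.0 and mx < 120.0:
        return "reliable"
    if mx <= 240.0:
        return "temporal_only"
    return "unreliable"


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def build_likelihoods(
    clean: CleanSeries,
    grid: WaterGrid,
    config: HmmConfig,
    detections: Optional[pd.DataFrame] = None,
    stations: Optional[pd.DataFrame] = None,
) -> tuple[np.ndarray, list[DailyObservation]]:
    """Per-day combined (depth x temperature x detection) likelihoods over
    the usable days of a cleaned series."""
    days = clean.usable_daily
    lik = np.empty((len(days), grid.n))
    for t, obs in enumerate(days):
        terms = [
            depth_likelihood(obs, grid, config.sigma_bathy),
            temperature_likelihood(obs, grid, config.sigma_temp),
        ]
        if detections is not None and stations is not None:
            terms.append(
                detection_likelihood(
                    obs.date, detections, stations, grid, config.sigma_det_m
                )
            )
        lik[t] = combine_likelihoods(*terms)
    return lik, days


def _daily_kernels(states, k_low, k_high, T):
    if states is None:
        return k_low
    return [k_high if states[t] else k_low for t in range(T - 1)]


def estimate_D(
    clean: CleanSeries,
    field: GriddedField,
    detections: Optional[DetectionSet] = None,
    config: HmmConfig = HmmConfig(),
    activity: Optional[ActivityStates] = None,
) -> PosteriorTrack:
    """Maximum-likelihood diffusion coefficient and the resulting track.

    Single-D: golden-section search on log D (5% relative tolerance).
    With behavioural switching (when the activity HMM converged): a
    Nelder-Mead refinement over (D_low, D_high) constrained to
    D_high >= D_low, initialised from the single-D fit; the daily kernel
    follows the decoded state of the origin day."""
    grid = WaterGrid(field, max_cells=config.max_cells)
    det_df = stations = None
    if detections is not None:
        det_df = detections.for_tag(clean.series.tag_id)
        stations = detections.stations
    lik, days = build_likelihoods(clean, grid, config, det_df, stations)
    if len(days) < 2:
        raise ValueError("need at least 2 usable days to fit a track")
    warnings: list[str] = []
    prior = grid.point_mass(clean.series.release[1], clean.series.release[2])
    if config.use_terminal_anchor and clean.series.recovery is not None:
        anchor = grid.point_mass(clean.series.recovery[1], clean.series.recovery[2])
        lik = lik.copy()
        lik[-1] = combine_likelihoods(lik[-1], anchor)

    kern_cache: dict[float, sparse.csr_matrix] = {}

    def kernel(d_coef: float) -> sparse.csr_matrix:
        key = round(float(d_coef), 6)
        if key not in kern_cache:
            kern_cache[key] = movement_kernel(key, grid)
        return kern_cache[key]

    def loglik_single(log_d: float) -> float:
        _, ll = forward_backward(lik, kernel(math.exp(log_d)), prior)
        return ll

    lo, hi = (math.log(v) for v in config.d_range)
    log_d = _golden_max(loglik_single, lo, hi, rel_tol=0.05)
    d_single = math.exp(log_d)
    d_fit = (d_single, d_single)
    states = None
    switching = False

    if config.switching and activity is not None and activity.converged:
        states = activity.states[: len(days)]
        if states.min() != states.max():  # both states actually occur
            switching = True

            def neg_ll(x: np.ndarray) -> float:
                dl, dh = math.exp(x[0]), math.exp(x[1])
                if dh < dl or not (
                    config.d_range[0] * 0.999 <= dl
                    and dh <= config.d_range[1] * 1.001
                ):
                    return 1e9
                ks = _daily_kernels(states, kernel(dl), kernel(dh), len(days))
                _, ll = forward_backward(lik, ks, prior)
                return -ll

            x0 = np.log([max(0.7 * d_single, config.d_range[0]),
                         min(1.5 * d_single, config.d_range[1])])
            res = optimize.minimize(
                neg_ll, x0, method="Nelder-Mead",
                options={"maxfev": 60, "xatol": 0.05, "fatol": 0.01},
            )
            if np.isfinite(res.fun) and res.fun < 1e8:
                d_fit = tuple(sorted(math.exp(v) for v in res.x))
            else:
                warnings.append("switching fit failed; single-D kernel kept")
                switching = False

    if switching:
        kernels = _daily_kernels(states, kernel(d_fit[0]), kernel(d_fit[1]), len(days))
    else:
        kernels = kernel(d_fit[0])
    post, ll = forward_backward(lik, kernels, prior, warnings)
    path = viterbi(lik, kernels, prior)
    vit = np.column_stack([grid.cell_lats[path], grid.cell_lons[path]])
    mean, modal = mean_and_modal_tracks(post, grid)
    vs_mean = haversine_km(vit[:, 0], vit[:, 1], mean[:, 0], mean[:, 1])
    vs_mode = haversine_km(vit[:, 0], vit[:, 1], modal[:, 0], modal[:, 1])
    track = PosteriorTrack(
        tag_id=clean.series.tag_id,
        dates=[d.date for d in days],
        grid=grid,
        posteriors=post,
        viterbi_track=vit,
        mean_track=mean,
        modal_track=modal,
        log_likelihood=ll,
        d_fit=d_fit,
        switching=switching,
        viterbi_vs_mean_km=np.atleast_1d(vs_mean),
        viterbi_vs_mode_km=np.atleast_1d(vs_mode),
        warnings=warnings,
    )
    track.reliability = validate_track(track)
    return track


def _golden_max(f, lo: float, hi: float, rel_tol: float = 0.05) -> float:
    """Golden-section maximisation on a 1-D interval (inputs already on
    the log scale, so ``rel_tol`` is a relative tolerance)."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > math.log(1.0 + rel_tol):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0
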