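"""Minimal "cell compass" model of persistent migration.

The model couples stochastic protrusive activity on a circular cell
contour (``n_markers`` markers) to an internal polarity axis through a
two-sided feedback:

* *polarity -> protrusions*: each frame a protrusive event nucleates
  with probability ``p_nuc``; with probability ``p_polarized`` its
  centre is drawn around the polarity axis (Gaussian, SD ``sigma_c``
  markers), otherwise uniformly on the contour.
* *protrusions -> polarity*: the axis marker ``c_axis`` is pulled
  toward protruding regions with a force proportional to the protrusion
  speed, mixed with a basal random drift by the feedback weight
  ``kappa``: ``c_axis(t+1) = c_axis(t) + kappa * g * F_prot
  + (1 - kappa) * F_basal``.

A single protrusive event is a fixed space-time morphodynamic template:
the convolution of a transfer function (edge response to a point-like
Cdc42 activation: local protrusion, wide lateral inhibition, a
bilateral travelling wave, and a central long-lasting inhibition, all
fading exponentially) with a Cdc42 "puff" (spatial Gaussian times
temporal exponential), normalised to zero sum so the cell area stays
constant on average.  Events superpose linearly on the map; the cell
centroid moves as the vector sum of the marker velocities.

Simulated maps and trajectories are analysed with exactly the same code
paths as experimental ones (persistence time, protrusive unicity,
alignment index), which makes the two feedback parameters measurable:
phase diagrams of the three observables over ``(p_polarized, kappa)``
serve as look-up tables inverted by :func:`estimate_parameters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import uniform_filter1d

from .morphomap import MorphodynamicMap
from .trajectory import (
    alignment_index,
    direction_autocorrelation,
    fit_persistence_time,
    step_directions,
)

__all__ = [
    "EventTemplateParams",
    "CompassParams",
    "SimulationResult",
    "PhaseDiagram",
    "ParameterEstimate",
    "make_transfer_function",
    "cdc42_puff",
    "single_event_template",
    "event_duration_frames",
    "event_footprint_markers",
    "natural_axis_path",
    "map_to_trajectory",
    "protrusion_force",
    "simulate",
    "simulation_observables",
    "unicity_index",
    "alignment_from_simulation",
    "phase_diagram",
    "estimate_parameters",
    "render_movie",
]


@dataclass
class EventTemplateParams:
    """Shape parameters of the single protrusive-event template.

    Spatial widths and the wave speed are in markers (and markers per
    frame); temporal constants in frames.  The numeric defaults are not
    measured quantities: they are calibrated so that the event footprint
    (|speed| above 10% of the peak) lasts about 10 frames (50 min at
    5 min/frame) and spans well under a quarter of the contour, matching
    the single localized protrusion/retraction cycles seen in
    low-persistence (nocodazole-like) morphodynamic maps.
    """

    amp_lateral_inhibition: float = 0.25   # A1, wide negative Gaussian
    sigma_wide: float = 22.0
    amp_protrusion: float = 1.0            # A2, narrow positive Gaussian
    sigma_narrow: float = 6.0
    amp_wave: float = 0.08                 # A3, bilateral travelling wave
    wave_speed: float = 1.0                # markers / frame
    amp_central_inhibition: float = 0.2    # A4, negative, Gaussian in time
    sigma_mid: float = 15.0
    tau_central: float = 8.0               # temporal Gaussian width of (iv)
    tau_lateral: float = 4.0               # exponential decay times
    tau_protrusion: float = 5.0
    tau_wave: float = 2.0
    sigma_puff: float = 5.0
    tau_puff: float = 3.0
    kernel_len: int = 30                   # frames kept for the kernel
    template_len: int = 30                 # frames kept after convolution

    def validate(self, n_markers: int) -> None:
        widths = (self.sigma_wide, self.sigma_narrow, self.sigma_mid, self.sigma_puff)
        if any(w <= 0 for w in widths):
            raise ValueError("spatial widths must be positive")
        if any(w > n_markers / 2 for w in widths):
            raise ValueError("spatial widths must not exceed half the contour")
        if min(self.tau_lateral, self.tau_protrusion, self.tau_wave,
               self.tau_central, self.tau_puff) <= 0:
            raise ValueError("temporal constants must be positive")


# Calibrated constants (see docs/methods.md): the natural-axis smoothing
# window makes the free polarity axis span the full contour in a few tens
# of frames (the ~4 h reorientation seen on round micropatterns); the
# axis gain converts the protrusion force into markers/frame such that,
# at kappa = 1, the axis reaches a pinned protrusion within one event
# duration.
AXIS_WINDOW_DEFAULT = 60
AXIS_GAIN_DEFAULT = 0.3


@dataclass
class CompassParams:
    """Full simulation parameters.

    ``p_polarized`` and ``kappa`` are the two feedback strengths in
    [0, 1]; ``p_nuc`` is the nucleation probability per frame (0.25),
    ``sigma_c`` the placement noise around the axis (5 markers, 1/20 of
    the contour); ``t_tot`` frames of ``dt`` minutes each.
    """

    p_polarized: float = 0.5
    kappa: float = 0.5
    p_nuc: float = 0.25
    sigma_c: float = 5.0
    n_markers: int = 100
    t_tot: int = 1000
    dt: float = 5.0
    axis_window: int = AXIS_WINDOW_DEFAULT
    axis_gain: float = AXIS_GAIN_DEFAULT
    force_mode: str = "sign"
    template: EventTemplateParams = field(default_factory=EventTemplateParams)
    seed: int | None = None

    def __post_init__(self):
        for name in ("p_polarized", "kappa", "p_nuc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be >= 0")
        if self.t_tot < 1:
            raise ValueError("t_tot must be >= 1")
        self.template.validate(self.n_markers)


@dataclass
class SimulationResult:
    """One simulated cell: map, polarity-axis track, and trajectory."""

    morphomap: MorphodynamicMap
    c_axis: np.ndarray          # axis marker index per frame, in [0, n)
    trajectory: np.ndarray      # (t_tot, 2) centroid positions
    params: CompassParams


@dataclass
class PhaseDiagram:
    """Observable grids over the two feedback parameters."""

    p_values: np.ndarray
    kappa_values: np.ndarray
    tau_hours: np.ndarray       # (n_p, n_kappa) mean persistence time
    unicity: np.ndarray
    alignment: np.ndarray
    tau_sd: np.ndarray
    unicity_sd: np.ndarray
    alignment_sd: np.ndarray
    replicates: int
    censored_frac: np.ndarray | None = None
    base_params: CompassParams | None = None


@dataclass
class ParameterEstimate:
    p_polarized: float
    kappa: float
    residual: float
    used_observables: tuple
    extrapolated: bool
    contours: dict = field(default_factory=dict, repr=False)


def _circ_gauss(offsets: np.ndarray, sigma: float, n: int) -> np.ndarray:
    d = np.abs(offsets)
    d = np.minimum(d, n - d)
    return np.exp(-0.5 * (d / sigma) ** 2)


def make_transfer_function(
    params: EventTemplateParams, n_markers: int = 100
) -> np.ndarray:
    """Edge response to a point-like activation, as a space-time kernel.

    ``kernel[s, t]`` for circular spatial offset ``s`` (centred on
    marker 0) and ``t >= 0`` frames sums four terms: (i) a wide negative
    Gaussian (lateral inhibition), (ii) a narrow positive Gaussian (the
    protrusion itself), (iii) a bilateral pair of narrow Gaussians whose
    centres travel at the wave speed, and (iv) a negative Gaussian in
    time centred on 0 (central long-lasting inhibition); the first three
    fade exponentially in time.
    """
    params.validate(n_markers)
    n = n_markers
    s = ((np.arange(n) + n // 2) % n) - n // 2  # circular offsets of each row
    t = np.arange(params.kernel_len)
    g_wide = _circ_gauss(s, params.sigma_wide, n)[:, None]
    g_narrow = _circ_gauss(s, params.sigma_narrow, n)[:, None]
    g_mid = _circ_gauss(s, params.sigma_mid, n)[:, None]
    fade1 = np.exp(-t / params.tau_lateral)[None, :]
    fade2 = np.exp(-t / params.tau_protrusion)[None, :]
    fade3 = np.exp(-t / params.tau_wave)[None, :]
    wave = np.zeros((n, params.kernel_len))
    for k, tk in enumerate(t):
        c = params.wave_speed * tk
        wave[:, k] = _circ_gauss(s - c, params.sigma_narrow, n) + _circ_gauss(
            s + c, params.sigma_narrow, n
        )
    kernel = (
        -params.amp_lateral_inhibition * g_wide * fade1
        + params.amp_protrusion * g_narrow * fade2
        + params.amp_wave * wave * fade3
        - params.amp_central_inhibition
        * g_mid
        * np.exp(-0.5 * (t / params.tau_central) ** 2)[None, :]
    )
    return kernel


def cdc42_puff(params: EventTemplateParams, n_markers: int = 100) -> np.ndarray:
    """Cdc42 signalling puff: spatial Gaussian times temporal exponential."""
    n = n_markers
    s = ((np.arange(n) + n // 2) % n) - n // 2
    t = np.arange(params.kernel_len)
    return _circ_gauss(s, params.sigma_puff, n)[:, None] * np.exp(-t / params.tau_puff)[None, :]


def single_event_template(
    params: EventTemplateParams | None = None, n_markers: int = 100
) -> np.ndarray:
    """Morphodynamic map of one protrusive event, zero-sum and peak-1.

    Convolves the transfer function with the Cdc42 puff (circularly in
    space, causally in time), truncates to ``template_len`` frames, then
    shifts to an exactly zero sum (constant mean cell area) and scales
    the peak protrusion speed to 1.
    """
    params = params or EventTemplateParams()
    kernel = make_transfer_function(params, n_markers)
    puff = cdc42_puff(params, n_markers)
    fk = np.fft.rfft(kernel, axis=0)
    fp = np.fft.rfft(puff, axis=0)
    n_t = kernel.shape[1] + puff.shape[1] - 1
    out = np.zeros((n_markers, n_t))
    # causal convolution in time of the space-convolved columns
    space_conv = np.fft.irfft(
        fk[:, :, None] * fp[:, None, :], n=n_markers, axis=0
    )  # (n, t_kernel, t_puff)
    for i in range(kernel.shape[1]):
        for j in range(puff.shape[1]):
            out[:, i + j] += space_conv[:, i, j]
    out = out[:, : params.template_len]
    # zero total sum: rescale the lighter-signed part rather than adding a
    # uniform offset, which would spread spurious activity over the whole
    # contour
    pos, neg = out[out > 0].sum(), -out[out < 0].sum()
    if pos > 0 and neg > 0:
        if neg >= pos:
            out[out < 0] *= pos / neg
        else:
            out[out > 0] *= neg / pos
    else:
        out -= out.mean()
    peak = out.max()
    if peak <= 0:
        raise ValueError("degenerate template: no positive (protrusive) part")
    return out / peak


def event_duration_frames(template: np.ndarray, frac: float = 0.1) -> int:
    """Frames whose peak |speed| exceeds ``frac`` of the template max."""
    thresh = frac * np.abs(template).max()
    return int(np.sum(np.abs(template).max(axis=0) > thresh))


def event_footprint_markers(template: np.ndarray, frac: float = 0.1) -> int:
    """Markers whose peak protrusive speed exceeds ``frac`` of the max.

    Measures the lateral extent of the protruding (positive) part of the
    event; the wide inhibitory surround is deliberately excluded.
    """
    thresh = frac * template.max()
    return int(np.sum(template.max(axis=1) > thresh))


def natural_axis_path(
    t_tot: int,
    n_markers: int = 100,
    window: int = AXIS_WINDOW_DEFAULT,
    rng=None,
):
    """Basal (feedback-free) wandering of the polarity axis.

    The axis position is a smoothed random function: i.i.d. values
    uniform on ``[0, 10 * n_markers)`` passed through a moving average
    of ``window`` frames.  The window is calibrated so the free axis
    typically spans a full contour turn within a 4 h (48-frame)
    reorientation timescale, matching cells confined on round patterns;
    the default sits at the diffusive (fast) end of that band.

    Returns
    -------
    c_natural : unwrapped axis position per frame (marker units)
    f_basal : per-frame drift ``c_natural(t+1) - c_natural(t)`` (last 0)
    """
    if not hasattr(rng, "uniform"):
        rng = np.random.default_rng(rng)
    u = rng.uniform(0.0, 10.0 * n_markers, size=t_tot)
    c_nat = uniform_filter1d(u, size=window, mode="nearest")
    f_basal = np.zeros(t_tot)
    f_basal[:-1] = np.diff(c_nat)
    return c_nat, f_basal


def map_to_trajectory(values: np.ndarray) -> np.ndarray:
    """Centroid trajectory implied by a morphodynamic map.

    The instantaneous centroid displacement is the average of the marker
    velocities along their radial directions,
    ``(1/n) * sum_i v_i(t) * (cos 2*pi*i/n, sin 2*pi*i/n)``.
    Returns one position per map column (first at the origin).
    """
    n, T = values.shape
    ang = 2 * np.pi * np.arange(n) / n
    units = np.column_stack([np.cos(ang), np.sin(ang)])
    steps = values.T @ units / n  # (T, 2)
    pos = np.zeros((T, 2))
    pos[1:] = np.cumsum(steps[:-1], axis=0)
    return pos


def _circular_sign(offsets: np.ndarray, n: int) -> np.ndarray:
    """Sign of the shortest circular path from 0 to each offset."""
    d = (offsets + n / 2.0) % n - n / 2.0
    return np.sign(d)


def protrusion_force(
    speeds: np.ndarray, c_axis: float, n: int, mode: str = "sign"
) -> float:
    """Pull of the current protrusions on the polarity axis.

    Only protruding markers (positive speed) pull; retractions do not.
    Two readings of the pull's geometry are supported:

    ``"sign"`` (default)
        Each protruding marker contributes its speed with the sign of
        the shortest circular path from the axis, independently of
        distance.  Markers straddling the axis cancel, so any single
        off-axis protrusion dominates the net force while it lasts and
        the axis reorients toward every stray event — the strongest
        form of "every protruding portion pulls, independently of
        position".

    ``"centroid"``
        The force is the protrusion-speed-weighted mean circular offset
        of the protruding markers from the axis, so the axis relaxes
        toward the centre of protrusive activity.  A transient stray
        protrusion deflects the axis only in proportion to its share of
        the total protrusive activity.
    """
    w = np.maximum(speeds, 0.0)
    offsets = (np.arange(n) - c_axis + n / 2.0) % n - n / 2.0
    if mode == "sign":
        return float(np.sum(w * np.sign(offsets)))
    if mode == "centroid":
        total = w.sum()
        if total <= 0:
            return 0.0
        return float(np.sum(w * offsets) / total)
    raise ValueError("mode must be 'centroid' or 'sign'")


def simulate(params: CompassParams) -> SimulationResult:
    """Run the full two-sided feedback simulation.

    Per frame: nucleate an event with probability ``p_nuc`` (centre
    polarized around the axis with probability ``p_polarized``, uniform
    otherwise) and superpose the event template on the map; then update
    the axis with the kappa-weighted mix of protrusion pull and basal
    drift.  Fixed seed gives a bit-identical result.
    """
    rng = np.random.default_rng(params.seed)
    n, T = params.n_markers, params.t_tot
    template = single_event_template(params.template, n)
    t_ev = template.shape[1]
    c_nat, f_basal = natural_axis_path(T, n, params.axis_window, rng)

    values = np.zeros((n, T))
    c_axis = np.zeros(T)
    c_axis[0] = c_nat[0] % n
    g = params.axis_gain
    for t in range(T):
        if rng.random() < params.p_nuc:
            if rng.random() < params.p_polarized:
                center = int(np.round(rng.normal(c_axis[t], params.sigma_c))) % n
            else:
                center = int(rng.integers(n))
            L = min(t_ev, T - t)
            values[:, t : t + L] += np.roll(template[:, :L], center, axis=0)
        if t + 1 < T:
            f_prot = protrusion_force(values[:, t], c_axis[t], n, params.force_mode)
            c_axis[t + 1] = (
                c_axis[t] + params.kappa * g * f_prot + (1 - params.kappa) * f_basal[t]
            ) % n

    mmap = MorphodynamicMap(values=values, dt=params.dt)
    traj = map_to_trajectory(values)
    return SimulationResult(morphomap=mmap, c_axis=c_axis, trajectory=traj, params=params)


_STRUCT8 = np.ones((3, 3), dtype=int)


def _count_components_circular(window: np.ndarray) -> int:
    """Connected components of a binary (markers x frames) window with
    the marker axis circular (row 0 adjacent to row n-1)."""
    lab, k = ndi.label(window, structure=_STRUCT8)
    if k < 2:
        return k
    top, bot = lab[0], lab[-1]
    if not (top.any() and bot.any()):
        return k
    parent = np.arange(k + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    w = window.shape[1]
    for j in range(w):
        a = top[j]
        if not a:
            continue
        for jj in (j - 1, j, j + 1):
            if 0 <= jj < w and bot[jj]:
                ra, rb = find(a), find(bot[jj])
                if ra != rb:
                    parent[rb] = ra
    return len({find(x) for x in range(1, k + 1)})


def unicity_index(
    mmap,
    window: int = 10,
    threshold_frac: float = 0.7,
    threshold_scope: str = "window",
) -> float:
    """Protrusive unicity: inverse of the mean number of simultaneous
    protrusions.

    A sliding window of ``window`` frames is binarized at
    ``threshold_frac`` of the maximal protrusion speed and the distinct
    protruding objects (8-connected, circular in space) are counted; the
    count is averaged over all windows containing at least one object.
    A single front at a time gives 1; two fronts everywhere give 0.5.
    A map with no protrusive values gives NaN.

    ``threshold_scope`` sets where the reference maximum is taken:
    ``"window"`` (default) compares simultaneous protrusions against the
    locally strongest one, so competing fronts are counted whatever the
    map-wide maximum happens to be; ``"map"`` uses one global threshold,
    under which chance superpositions of events dominate the count.
    """
    values = mmap.values if isinstance(mmap, MorphodynamicMap) else np.asarray(mmap, float)
    n, T = values.shape
    if T < window:
        raise ValueError("map shorter than the sliding window")
    if threshold_scope not in ("window", "map"):
        raise ValueError("threshold_scope must be 'window' or 'map'")
    vmax = np.nanmax(values)
    if not np.isfinite(vmax) or vmax <= 0:
        return np.nan
    with np.errstate(invalid="ignore"):
        counts = []
        for t in range(T - window + 1):
            win = values[:, t : t + window]
            ref = np.nanmax(win) if threshold_scope == "window" else vmax
            if not ref > 0:
                continue
            binary = win > threshold_frac * ref
            if not binary.any():
                continue
            counts.append(_count_components_circular(binary))
    if not counts:
        return np.nan
    return float(1.0 / np.mean(counts))


def alignment_from_simulation(result: SimulationResult) -> float:
    """Alignment index between the polarity axis and the motion direction.

    The axis direction is ``2 * pi * c_axis / n``; the motion direction
    is the per-frame heading of the centroid trajectory; frames with
    zero displacement are skipped.  Returns the angular dispersion
    ``r`` in [0, 1].
    """
    n = result.params.n_markers
    axis_angles = 2 * np.pi * result.c_axis / n
    motion = step_directions(result.trajectory)
    return alignment_index(axis_angles[: len(motion)], motion)


def simulation_observables(result: SimulationResult, fit_frac: float = 1.0 / 3.0) -> dict:
    """Persistence time (hours), unicity, and alignment of one run.

    Censored persistence fits (trajectory straighter than the run can
    resolve) are reported at the censoring bound ``t_tot * dt``.
    """
    p = result.params
    duration = p.t_tot * p.dt
    ac = direction_autocorrelation(result.trajectory, dt=p.dt)
    fit = fit_persistence_time(ac, fit_frac=fit_frac, track_duration=duration, tau_bound=duration)
    tau_h = fit.tau / 60.0 if np.isfinite(fit.tau) else np.nan
    return {
        "tau_hours": tau_h,
        "tau_censored": bool(fit.tau_censored),
        "unicity": unicity_index(result.morphomap),
        "alignment": alignment_from_simulation(result),
    }


def _derived_seed(base_seed: int, i: int, j: int, r: int) -> int:
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(i, j, r))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def phase_diagram(
    p_values=None,
    kappa_values=None,
    replicates: int = 20,
    base_params: CompassParams | None = None,
    base_seed: int = 0,
    progress: bool = False,
) -> PhaseDiagram:
    """Observable look-up tables over the ``(p_polarized, kappa)`` grid.

    Every grid node runs ``replicates`` independent simulations with
    seeds derived deterministically from ``base_seed`` and the node and
    replicate indices, then averages persistence time, unicity, and
    alignment.  The default grid is 11 x 11 over [0, 1]^2.
    """
    p_values = np.asarray(p_values if p_values is not None else np.linspace(0, 1, 11), float)
    kappa_values = np.asarray(
        kappa_values if kappa_values is not None else np.linspace(0, 1, 11), float
    )
    if p_values.min() < 0 or p_values.max() > 1 or kappa_values.min() < 0 or kappa_values.max() > 1:
        raise ValueError("grid must lie within [0, 1]^2")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    base = base_params or CompassParams()
    shape = (len(p_values), len(kappa_values))
    tau = np.empty(shape)
    uni = np.empty(shape)
    ali = np.empty(shape)
    tau_sd = np.empty(shape)
    uni_sd = np.empty(shape)
    ali_sd = np.empty(shape)
    cens = np.empty(shape)
    iterator = enumerate(p_values)
    if progress:
        from tqdm import tqdm  # pragma: no cover

        iterator = tqdm(list(iterator), desc="phase diagram")  # pragma: no cover
    for i, p in iterator:
        for j, k in enumerate(kappa_values):
            obs = []
            for r in range(replicates):
                params = replace(
                    base, p_polarized=float(p), kappa=float(k), seed=_derived_seed(base_seed, i, j, r)
                )
                obs.append(simulation_observables(simulate(params)))
            t = np.array([o["tau_hours"] for o in obs])
            u = np.array([o["unicity"] for o in obs])
            a = np.array([o["alignment"] for o in obs])
            tau[i, j], tau_sd[i, j] = np.nanmean(t), np.nanstd(t)
            uni[i, j], uni_sd[i, j] = np.nanmean(u), np.nanstd(u)
            ali[i, j], ali_sd[i, j] = np.nanmean(a), np.nanstd(a)
            cens[i, j] = np.mean([o["tau_censored"] for o in obs])
    return PhaseDiagram(
        p_values=p_values,
        kappa_values=kappa_values,
        tau_hours=tau,
        unicity=uni,
        alignment=ali,
        tau_sd=tau_sd,
        unicity_sd=uni_sd,
        alignment_sd=ali_sd,
        replicates=replicates,
        censored_frac=cens,
        base_params=base,
    )


def estimate_parameters(
    diagram: PhaseDiagram,
    tau_hours: float | None = None,
    unicity: float | None = None,
    alignment: float | None = None,
    refine: int = 201,
    smooth_sigma: float = 0.6,
) -> ParameterEstimate:
    """Invert the phase diagrams for measured observables.

    Minimises ``sum_obs ((sim - measured) / spread_obs)^2`` over the
    parameter square, with each observable field interpolated bilinearly
    between grid nodes and ``spread_obs`` the across-grid standard
    deviation of that observable (so differently scaled observables
    weigh comparably).  A missing alignment (e.g. a dispersed Golgi
    makes it unmeasurable) simply drops that term, flagged in
    ``used_observables``.  Measured values outside the simulated range
    give a nearest-boundary estimate flagged ``extrapolated``.

    ``smooth_sigma`` applies a mild Gaussian filter (in grid-node
    units) to each look-up table before interpolation.  The tables are
    Monte-Carlo means, and where the objective valley is shallow the
    raw argmin rides node-level noise; smoothing at sub-node scale
    suppresses that jitter without displacing the broad structure.
    Set it to 0 for the raw tables (then a measurement equal to a
    node's values returns that node exactly).

    Iso-contours of each used observable at its measured level are
    returned in grid coordinates for plotting the classic
    crossing-lines construction.
    """
    from scipy.interpolate import RegularGridInterpolator
    from scipy.ndimage import gaussian_filter
    from skimage import measure as skmeasure

    fields = {
        "tau_hours": (diagram.tau_hours, tau_hours),
        "unicity": (diagram.unicity, unicity),
        "alignment": (diagram.alignment, alignment),
    }
    used = [k for k, (_, m) in fields.items() if m is not None]
    if len(used) < 2:
        raise ValueError("need at least two measured observables")

    pf = np.linspace(diagram.p_values[0], diagram.p_values[-1], refine)
    kf = np.linspace(diagram.kappa_values[0], diagram.kappa_values[-1], refine)
    PP, KK = np.meshgrid(pf, kf, indexing="ij")
    pts = np.column_stack([PP.ravel(), KK.ravel()])

    objective = np.zeros(PP.shape)
    extrapolated = False
    contours: dict = {}
    for name in used:
        grid, measured = fields[name]
        spread = np.nanstd(grid)
        if not np.isfinite(spread) or spread == 0:
            spread = 1.0
        table = gaussian_filter(grid, smooth_sigma, mode="nearest") if smooth_sigma else grid
        interp = RegularGridInterpolator(
            (diagram.p_values, diagram.kappa_values), table, method="linear"
        )
        fine = interp(pts).reshape(PP.shape)
        objective += ((fine - measured) / spread) ** 2
        if measured < np.nanmin(grid) or measured > np.nanmax(grid):
            extrapolated = True
        paths = skmeasure.find_contours(fine, measured)
        contours[name] = [
            np.column_stack([np.interp(c[:, 0], np.arange(refine), pf),
                             np.interp(c[:, 1], np.arange(refine), kf)])
            for c in paths
        ]
    best = np.unravel_index(np.argmin(objective), PP.shape)
    return ParameterEstimate(
        p_polarized=float(pf[best[0]]),
        kappa=float(kf[best[1]]),
        residual=float(objective[best]),
        used_observables=tuple(used),
        extrapolated=extrapolated,
        contours=contours,
    )


def render_movie(result: SimulationResult, initial_contour=None, speed_scale: float = 1.0):
    """Contour movie of a simulated cell (visualisation only).

    Delegates to :func:`cellcompass.synthetic.gen_contour_movie`,
    evolving an elastic contour under the simulated map.
    """
    from .synthetic import circle_contour, gen_contour_movie

    if initial_contour is None:
        initial_contour = circle_contour(radius=50.0, n_vertices=result.params.n_markers)
    values = result.morphomap.values * speed_scale
    return gen_contour_movie(values, initial_contour)
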