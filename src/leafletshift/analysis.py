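"""Quantification chain for single-channel current traces.

Mirrors the analysis applied to the recordings being emulated: the standard
deviation of the current as the scalar activity measure, normalized amplitude
histograms with Gaussian-mixture decomposition (levels whose peaks thermal
noise cannot separate are reported as one convolved component), substate
probabilities, dwell-averaged level currents feeding linear I–V conductance
fits, and the equivalent-voltage-shift (delta_U) estimator that superimposes
the activity–voltage curves of two conditions.

The delta_U estimator exploits the exponential activity law: with open-level
occupancies proportional to exp(D / V_e), the log of the gating-driven
current sd is linear in the driving potential D = |V| + delta_U with a
condition-independent slope, so a common-slope fit of two conditions turns
the intercept difference into delta_U.  Two physically motivated corrections
are available and used by the pipeline: the ohmic amplitude factor (level
currents scale as g|V|) is divided out before taking the log, and the
known thermal-noise floor is subtracted in variance, since both otherwise
bend the low- and high-voltage ends of the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .traceio import TraceRecording

__all__ = [
    "AmplitudeHistogram",
    "MixtureComponent",
    "SigmaCurve",
    "IVFit",
    "DeltaUEstimate",
    "LevelReadings",
    "SubstateProbabilities",
    "MixtureConvergenceError",
    "component_level_map",
    "current_sigma",
    "build_histogram",
    "fit_mixture",
    "substate_probabilities",
    "relative_change",
    "extract_level_currents",
    "fit_iv",
    "fit_sigma_voltage",
    "estimate_delta_u",
    "fit_sigma_concentration",
]


class MixtureConvergenceError(RuntimeError):
    """EM failed to converge; carries the final log-likelihood."""

    def __init__(self, log_likelihood: float):
        super().__init__(
            f"EM did not converge (final log-likelihood {log_likelihood:.6g})"
        )
        self.log_likelihood = log_likelihood


def current_sigma(rec: TraceRecording) -> float:
    """Sample standard deviation of the full trace, in pA."""
    if rec.n_samples < 2:
        raise ValueError("need at least two samples")
    return float(np.std(rec.currents, ddof=1))


@dataclass(frozen=True)
class AmplitudeHistogram:
    """Normalized amplitude histogram (unit integral) of a current trace."""

    bin_edges: np.ndarray  # pA
    densities: np.ndarray  # 1/pA

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "densities", dens)
        if edges.size != dens.size + 1:
            raise ValueError("need len(bin_edges) == len(densities) + 1")
        if np.any(dens < 0):
            raise ValueError("densities must be non-negative")
        integral = float(np.sum(dens * np.diff(edges)))
        if abs(integral - 1.0) > 1e-9:
            raise ValueError(f"histogram integral {integral} != 1")


def build_histogram(rec: TraceRecording, min_bins: int = 50) -> AmplitudeHistogram:
    """Amplitude histogram with Freedman–Diaconis binning, clamped to >= 50 bins."""
    x = rec.currents
    if x.size < 100:
        raise ValueError("need at least 100 samples for a histogram")
    span = float(np.ptp(x))
    if span == 0.0:
        raise ValueError("degenerate trace: zero amplitude range")
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr > 0:
        width = 2.0 * iqr / x.size ** (1.0 / 3.0)
        n_bins = max(min_bins, int(math.ceil(span / width)))
    else:
        n_bins = min_bins
    densities, edges = np.histogram(x, bins=n_bins, density=True)
    return AmplitudeHistogram(bin_edges=edges, densities=densities)


@dataclass(frozen=True)
class MixtureComponent:
    """One (possibly merged) Gaussian peak of the amplitude histogram.

    ``merged_labels`` holds the rank indices (0 = closest to baseline) of the
    original mixture components this peak aggregates; a convolved
    closed/first-substate peak carries {0, 1}.
    """

    weight: float
    mean: float  # pA
    sd: float  # pA
    merged_labels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0 + 1e-12):
            raise ValueError("weight must be a probability")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def fit_mixture(
    rec: TraceRecording,
    k_max: int = 6,
    merge_sd_factor: float = 3.0,
    max_fit_samples: int = 100_000,
    random_state: int = 0,
) -> list[MixtureComponent]:
    """Gaussian-mixture decomposition of the amplitude distribution.

    Fits mixtures with 1..k_max components by EM, selects k by BIC, sorts
    components by descending mean (baseline first, deepest substate last) and
    merges adjacent components whose means differ by less than
    ``merge_sd_factor`` times their pooled sd — the situation where thermal
    noise makes two levels indistinguishable on the histogram.  Weights of a
    merged peak are summed and its ``merged_labels`` records the constituent
    rank indices.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = rec.currents.reshape(-1, 1)
    if x.shape[0] > max_fit_samples:
        # deterministic thinning keeps EM affordable on long traces
        stride = x.shape[0] // max_fit_samples + 1
        x = x[::stride]
    best = None
    best_bic = np.inf
    for k in range(1, k_max + 1):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=1,
            max_iter=500,
            random_state=random_state,
            reg_covar=1e-6,
        ).fit(x)
        if not gmm.converged_:
            raise MixtureConvergenceError(float(gmm.lower_bound_))
        bic = gmm.bic(x)
        if bic < best_bic:
            best_bic = bic
            best = gmm
    order = np.argsort(-best.means_[:, 0])  # descending mean: baseline first
    weights = best.weights_[order]
    means = best.means_[order, 0]
    sds = np.sqrt(best.covariances_[order, 0])

    merged: list[MixtureComponent] = []
    for rank in range(len(means)):
        comp = MixtureComponent(
            weight=float(weights[rank]),
            mean=float(means[rank]),
            sd=float(sds[rank]),
            merged_labels=frozenset({rank}),
        )
        if merged:
            prev = merged[-1]
            pooled = math.sqrt(
                (prev.weight * prev.sd**2 + comp.weight * comp.sd**2)
                / (prev.weight + comp.weight)
            )
            if abs(prev.mean - comp.mean) < merge_sd_factor * pooled:
                w = prev.weight + comp.weight
                mean = (prev.weight * prev.mean + comp.weight * comp.mean) / w
                var = (
                    prev.weight * (prev.sd**2 + prev.mean**2)
                    + comp.weight * (comp.sd**2 + comp.mean**2)
                ) / w - mean**2
                merged[-1] = MixtureComponent(
                    weight=float(w),
                    mean=float(mean),
                    sd=float(math.sqrt(max(var, 1e-12))),
                    merged_labels=prev.merged_labels | comp.merged_labels,
                )
                continue
        merged.append(comp)
    return merged


@dataclass(frozen=True)
class SubstateProbabilities:
    """Per level-group occupation probabilities from mixture areas."""

    groups: dict  # tuple of level indices -> probability
    flagged: tuple  # components that matched no level

    def probability(self, *levels: int) -> float:
        return self.groups.get(tuple(sorted(levels)), 0.0)

    def probability_at_least(self, level: int) -> float:
        """Total probability of groups whose lowest member is >= level."""
        return sum(p for g, p in self.groups.items() if min(g) >= level)


def component_level_map(
    components: list[MixtureComponent], level_currents: np.ndarray
) -> list[tuple[int, ...]]:
    """Conductance levels attracted by each component, by nearest-mean matching.

    ``level_currents`` gives the expected mean current of levels 0..K at the
    trace's holding potential.  Entry i is the (possibly empty) tuple of
    levels whose expected current lies closest to component i's mean; a
    convolved (0, 1) peak attracts both.  Two components competing for the
    same single level is reported as an error.
    """
    level_currents = np.asarray(level_currents, dtype=float)
    comp_means = np.array([c.mean for c in components])
    # each component's nearest level; a collision means the fit is ambiguous
    nearest_level = [int(np.argmin(np.abs(level_currents - m))) for m in comp_means]
    if len(set(nearest_level)) != len(nearest_level):
        clash = [l for l in nearest_level if nearest_level.count(l) > 1]
        raise ValueError(
            f"ambiguous assignment: multiple components map to level(s) {sorted(set(clash))}"
        )
    # each level's nearest component defines the level grouping
    owner = [int(np.argmin(np.abs(comp_means - i))) for i in level_currents]
    return [
        tuple(l for l, o in enumerate(owner) if o == ci)
        for ci in range(len(components))
    ]


def substate_probabilities(
    components: list[MixtureComponent], level_currents: np.ndarray
) -> SubstateProbabilities:
    """Assign mixture areas to conductance levels by nearest-mean matching.

    A component's probability covers the set of levels it attracts (see
    :func:`component_level_map`); components that attract no level are
    flagged.
    """
    level_map = component_level_map(components, level_currents)
    groups: dict[tuple[int, ...], float] = {}
    flagged = []
    for comp, levels in zip(components, level_map):
        if not levels:
            flagged.append(comp)
            continue
        groups[levels] = groups.get(levels, 0.0) + comp.weight
    return SubstateProbabilities(groups=groups, flagged=tuple(flagged))


def relative_change(p_control: float, p_treated: float) -> float:
    """Percent change of a substate probability relative to control."""
    if p_control <= 0:
        raise ValueError("control probability must be positive")
    return 100.0 * (p_treated - p_control) / p_control


@dataclass(frozen=True)
class LevelReadings:
    """Dwell-averaged current readings per mixture component (level group)."""

    readings: dict  # tuple of rank labels -> np.ndarray of dwell means (pA)
    unusable: tuple  # groups with fewer than min_readings dwell means
    min_readings: int


def extract_level_currents(
    rec: TraceRecording,
    components: list[MixtureComponent],
    min_readings: int = 20,
    min_run_samples: int = 5,
) -> LevelReadings:
    """Idealize a trace against mixture means and collect dwell-mean currents.

    Every sample is assigned to the nearest component mean; maximal runs of a
    constant assignment at least ``min_run_samples`` long count as dwells, and
    each dwell contributes its mean current as one reading.  Groups with fewer
    than ``min_readings`` readings are reported as unusable (following the
    rule that an I–V point needs more than 20 readings), but their readings
    are still returned.
    """
    if min_readings < 1:
        raise ValueError("min_readings must be positive")
    means = np.array([c.mean for c in components])
    order = np.argsort(means)
    boundaries = (means[order][1:] + means[order][:-1]) / 2.0
    assigned = order[np.digitize(rec.currents, boundaries)]
    change = np.flatnonzero(np.diff(assigned)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [assigned.size]])
    readings: dict[tuple[int, ...], list[float]] = {
        tuple(sorted(c.merged_labels)): [] for c in components
    }
    keys = [tuple(sorted(c.merged_labels)) for c in components]
    for s, e in zip(starts, ends):
        if e - s < min_run_samples:
            continue
        readings[keys[assigned[s]]].append(float(np.mean(rec.currents[s:e])))
    out = {k: np.asarray(v) for k, v in readings.items()}
    unusable = tuple(k for k, v in out.items() if v.size < min_readings)
    return LevelReadings(readings=out, unusable=unusable, min_readings=min_readings)


@dataclass(frozen=True)
class IVFit:
    """Linear current–voltage fit; the slope magnitude is the conductance."""

    slope: float  # nS, positive
    intercept: float  # pA
    slope_sem: float  # nS
    n_points: int
    r_squared: float


def fit_iv(points: list[tuple[float, float]]) -> IVFit:
    """Ordinary least squares on (holding potential mV, current pA) points.

    Currents are signed (downward, negative at negative potentials); the
    conductance is reported as the positive slope magnitude in nS.
    """
    v = np.array([p[0] for p in points], dtype=float)
    i = np.array([p[1] for p in points], dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("need at least two distinct voltages")
    res = stats.linregress(v, i)
    sem = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return IVFit(
        slope=abs(float(res.slope)),
        intercept=float(res.intercept),
        slope_sem=sem,
        n_points=int(v.size),
        r_squared=float(res.rvalue) ** 2,
    )


@dataclass(frozen=True)
class SigmaCurve:
    """Activity–voltage curve: current sd (pA) per holding potential (mV)."""

    points: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        for v, s in self.points:
            if not (math.isfinite(v) and math.isfinite(s)):
                raise ValueError("curve points must be finite")
            if s <= 0:
                raise ValueError("sigma values must be positive")

    @property
    def voltages(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass(frozen=True)
class LogLinearFit:
    intercept: float
    slope: float  # per mV
    r_squared: float
    slope_sem: float


def fit_sigma_voltage(curve: SigmaCurve) -> LogLinearFit:
    """Least-squares line through ln sigma vs |V| (the exponential activity law)."""
    v = np.abs(curve.voltages)
    if np.unique(v).size < 3:
        raise ValueError("need at least three distinct voltages")
    res = stats.linregress(v, np.log(curve.sigmas))
    return LogLinearFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue) ** 2,
        slope_sem=float(res.stderr),
    )


@dataclass(frozen=True)
class DeltaUEstimate:
    """Equivalent holding-potential shift between two conditions."""

    delta_u: float  # mV; positive = treated behaves as if |V| were larger
    sem: float  # mV
    method: dict = field(default_factory=dict)


def _activity_log(
    sigmas: np.ndarray,
    abs_v: np.ndarray,
    noise_sd: float | None,
    drive_exponent: float,
) -> np.ndarray:
    var = sigmas**2
    if noise_sd is not None:
        # keep the log defined when a point sits at the noise floor
        var = np.maximum(var - noise_sd**2, 0.05 * var)
    return 0.5 * np.log(var) - drive_exponent * np.log(abs_v)


def estimate_delta_u(
    control: SigmaCurve,
    treated: SigmaCurve,
    noise_sd: float | None = None,
    drive_exponent: float = 1.0,
    min_slope: float = 1e-6,
    n_bootstrap: int = 200,
    method: str = "analytic",
    seed: int = 0,
) -> DeltaUEstimate:
    """Equivalent voltage shift from superimposed activity–voltage curves.

    Fits the common-slope log-linear model y = a_c + b(|V| + delta_U * t)
    jointly to both conditions (t = 1 for treated) and returns
    delta_U = (a_t - a_c)/b, where y is ln sigma corrected for the ohmic
    amplitude factor |V|^drive_exponent and, when ``noise_sd`` is given, for
    the additive noise floor.  Setting ``drive_exponent=0`` and
    ``noise_sd=None`` recovers the plain ln sigma vs |V| fit.  The sem comes
    from first-order error propagation of the OLS covariance, or from a
    ``method="bootstrap"`` resampling of points when each curve has >= 5
    voltages.
    """
    for curve in (control, treated):
        if np.unique(np.abs(curve.voltages)).size < 3:
            raise ValueError("each curve needs at least three distinct voltages")
    vc, vt = np.abs(control.voltages), np.abs(treated.voltages)
    if vc.min() > vt.max() or vt.min() > vc.max():
        raise ValueError("voltage ranges of the two curves do not overlap")

    def fit(points_c, points_t):
        yc = _activity_log(points_c[:, 1], points_c[:, 0], noise_sd, drive_exponent)
        yt = _activity_log(points_t[:, 1], points_t[:, 0], noise_sd, drive_exponent)
        x = np.concatenate([points_c[:, 0], points_t[:, 0]])
        tflag = np.concatenate([np.zeros(len(yc)), np.ones(len(yt))])
        y = np.concatenate([yc, yt])
        X = np.column_stack([np.ones_like(x), x, tflag])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        a, b, c = beta
        if abs(b) < min_slope:
            raise ValueError(f"common slope |b|={abs(b):.2e} below tolerance")
        resid = y - X @ beta
        dof = len(y) - 3
        if dof > 0:
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            var_delta = (
                cov[2, 2] / b**2
                + c**2 * cov[1, 1] / b**4
                - 2 * c * cov[1, 2] / b**3
            )
            sem = math.sqrt(max(var_delta, 0.0))
        else:
            sem = 0.0
        return c / b, sem

    pc = np.column_stack([vc, control.sigmas])
    pt = np.column_stack([vt, treated.sigmas])
    delta, sem = fit(pc, pt)
    info = {
        "estimator": "common-slope log-linear shift",
        "drive_exponent": drive_exponent,
        "noise_sd": noise_sd,
        "sem_method": "propagation",
    }
    if method == "bootstrap":
        if min(len(pc), len(pt)) < 5:
            raise ValueError("bootstrap sem needs >= 5 voltages per curve")
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_bootstrap):
            bc = pc[rng.integers(0, len(pc), len(pc))]
            bt = pt[rng.integers(0, len(pt), len(pt))]
            try:
                d, _ = fit(bc, bt)
            except (ValueError, np.linalg.LinAlgError):
                continue
            draws.append(d)
        sem = float(np.std(draws, ddof=1)) if len(draws) > 1 else sem
        info["sem_method"] = f"bootstrap({len(draws)})"
    return DeltaUEstimate(delta_u=float(delta), sem=float(sem), method=info)


def fit_sigma_concentration(
    points: list[tuple[float, float]], v_applied: float
) -> LogLinearFit:
    """Least-squares line through ln sigma vs amphiphile concentration.

    ``points`` are (concentration in uM, sigma in pA) at a fixed holding
    potential; linearity of ln sigma in concentration is the signature of a
    surface potential that grows linearly with the dose.
    """
    c = np.array([p[0] for p in points], dtype=float)
    s = np.array([p[1] for p in points], dtype=float)
    if np.any(s <= 0):
        raise ValueError("sigma values must be positive")
    if np.unique(c).size < 3:
        raise ValueError("need at least three distinct concentrations")
    res = stats.linregress(c, np.log(s))
    return LogLinearFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue) ** 2,
        slope_sem=float(res.stderr),
    )
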