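"""Synthetic parcellated BOLD data with planted community switching.

The generator emulates the structure of a resting-state acquisition after
parcellation: 200 regions × 300 timepoints at TR = 1 s, eight canonical
networks, band-limited (0.01–0.1 Hz) correlated signals.  Community
structure is planted per window: every region follows its network's latent
signal, and selected regions switch community at chosen between-window
transitions, either jointly (cohesive groups, same source and destination)
or alone (disjoint movers).  The planted assignment matrix and event list
form the ground truth against which recovery of the full pipeline is
scored, and the exact reconfiguration metrics of the truth are the oracle
for metric tests.

Cohorts add phenotype tables modelled on a two-group fatigue study (155
patients, 48 controls) with configurable standardized metric–fatigue effect
sizes in the patient group only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netreconf.communities import AssignmentMatrix
from netreconf.io import DMT_CATEGORIES, NETWORKS, AtlasLabels, ParcellatedSeries
from netreconf.metrics import METRIC_NAMES, ReconfigMetrics, compute_metrics
from netreconf.windows import WindowSpec, make_windows

BAND_HZ = (0.01, 0.1)


def default_atlas(n_regions: int = 200, n_networks: int = 8) -> AtlasLabels:
    """Round-robin-free atlas: contiguous blocks of regions per network."""
    ids = [f"R{i + 1:03d}" for i in range(n_regions)]
    per = int(np.ceil(n_regions / n_networks))
    mapping = {rid: NETWORKS[min(i // per, n_networks - 1)] for i, rid in enumerate(ids)}
    return AtlasLabels(mapping)


@dataclass(frozen=True)
class Event:
    """One planted switching event at a between-window transition."""

    transition: int
    nodes: tuple
    source: int
    dest: int
    kind: str  # "cohesive" | "disjoint"


@dataclass
class PlantedTruth:
    """Ground-truth assignments, the events that produced them, and coupling."""

    assignments: AssignmentMatrix
    events: list
    coupling: float
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        for ev in self.events:
            if ev.kind == "cohesive" and len(ev.nodes) < 2:
                raise ValueError(f"cohesive event with {len(ev.nodes)} node(s): {ev}")
            if ev.kind == "disjoint" and len(ev.nodes) != 1:
                raise ValueError(f"disjoint event with {len(ev.nodes)} node(s): {ev}")

    @property
    def n_windows(self) -> int:
        return self.assignments.n_windows


def events_from_assignments(assignments: AssignmentMatrix) -> list:
    """Recover the event list implied by an assignment matrix.

    Movers at the same transition with the same source and destination form
    one cohesive event; lone movers form disjoint events — the same rule the
    metric layer uses, so planted events are consistent by construction.
    """
    labels = assignments.labels
    events = []
    for t in range(assignments.n_windows - 1):
        src, dst = labels[:, t], labels[:, t + 1]
        groups: dict = {}
        for i in np.where(src != dst)[0]:
            groups.setdefault((int(src[i]), int(dst[i])), []).append(int(i))
        for (s, d), members in sorted(groups.items()):
            kind = "cohesive" if len(members) >= 2 else "disjoint"
            events.append(Event(t, tuple(members), s, d, kind))
    return events


def make_planted_truth(seed: int, n_regions: int = 200, n_windows: int = 25,
                       n_communities: int = 8, atlas: AtlasLabels | None = None,
                       n_disjoint_movers: int = 40, n_cohesive_groups: int = 8,
                       min_dwell: int = 4, max_mean_extra: float = 8.0,
                       coupling: float = 0.8) -> PlantedTruth:
    """Plant per-node switching schedules on top of the static atlas labels.

    ``n_disjoint_movers`` single regions and ``n_cohesive_groups`` groups of
    2–3 regions (sharing a source network) each follow a renewal schedule:
    consecutive switches are separated by at least ``min_dwell`` windows
    plus a Poisson-distributed extra dwell whose mean is drawn per unit from
    [0, max_mean_extra], so switch counts vary widely across movers.  Every
    switch relabels the unit to a random different community, persisting
    until the next switch; the remaining regions keep their static label
    throughout.

    The minimum dwell keeps every planted visit at or above the sliding
    window's own timescale — sub-window visits would plant structure the
    windowed pipeline cannot resolve even in principle — and switches avoid
    the first and last transition, whose single-sided context makes them
    intrinsically ambiguous.
    """
    rng = np.random.default_rng(seed)
    atlas = atlas if atlas is not None else default_atlas(n_regions, n_communities)
    region_ids = list(atlas.mapping)[:n_regions]
    init = atlas.to_int_labels(region_ids)
    labels = np.tile(init[:, None], (1, n_windows))

    nodes = rng.permutation(n_regions)
    cursor = 0
    units = []  # each unit: list of node indices moving together
    for _ in range(n_cohesive_groups):
        size = int(rng.integers(2, 4))
        if cursor + size > n_regions:
            break
        group = [int(i) for i in nodes[cursor:cursor + size]]
        cursor += size
        # cohesive movers must share a source: align the group to one home label
        home = init[group[0]]
        for i in group:
            labels[i, :] = home
        units.append(group)
    for _ in range(n_disjoint_movers):
        if cursor >= n_regions:
            break
        units.append([int(nodes[cursor])])
        cursor += 1

    last_transition = n_windows - 3  # keep switches off the boundary transitions
    for unit in units:
        lam = rng.uniform(0.0, max_mean_extra)
        t = 1 + int(rng.poisson(lam / 2.0))
        transitions = []
        while t <= last_transition:
            transitions.append(t)
            t += min_dwell + int(rng.poisson(lam))
        for t in transitions:
            cur = labels[unit[0], t]
            choices = [c for c in range(1, n_communities + 1) if c != cur]
            new = int(rng.choice(choices))
            for i in unit:
                labels[i, t + 1:] = new

    am = AssignmentMatrix(labels, n_communities, region_ids)
    return PlantedTruth(am, events_from_assignments(am), coupling, seed)


def _band_limited(rng: np.random.Generator, n_series: int, n_timepoints: int,
                  tr_seconds: float, band=BAND_HZ) -> np.ndarray:
    """Unit-variance noise filtered to the given frequency band."""
    white = rng.standard_normal((n_series, n_timepoints))
    X = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    X[:, ~keep] = 0.0
    out = np.fft.irfft(X, n=n_timepoints, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _membership_per_sample(truth: PlantedTruth, n_timepoints: int, tr_seconds: float,
                           spec: WindowSpec) -> np.ndarray:
    """Map each sample to the truth column whose window it predominantly feeds.

    A planted transition between windows w and w+1 takes effect at the
    sample midway between the two windows' centres, so every truth column is
    the majority membership of its own (overlapping) window.
    """
    bounds = make_windows(n_timepoints, tr_seconds, spec)
    if len(bounds) != truth.n_windows:
        raise ValueError(
            f"geometry mismatch: series implies {len(bounds)} windows "
            f"({n_timepoints} samples, TR {tr_seconds}s, {spec}), truth provides "
            f"{truth.n_windows}")
    L = spec.length_samples(tr_seconds)
    centres = [s + L / 2.0 for s, _ in bounds]
    boundaries = [int(round((centres[w] + centres[w + 1]) / 2.0))
                  for w in range(len(bounds) - 1)]
    widx = np.searchsorted(np.asarray(boundaries), np.arange(n_timepoints), side="right")
    return truth.assignments.labels[:, widx]  # (n_regions, n_timepoints)


def generate_subject(truth: PlantedTruth, subject_id: str = "sim",
                     n_timepoints: int = 300, tr_seconds: float = 1.0,
                     band=BAND_HZ, window_spec: WindowSpec = WindowSpec(),
                     seed: int | np.random.Generator = 0) -> ParcellatedSeries:
    """Band-limited signals realizing the planted community structure.

    Each community carries an independent band-limited latent; region i at
    time t emits sqrt(ρ)·latent of its planted community at t plus
    sqrt(1−ρ)·independent band-limited noise, with ρ = ``truth.coupling``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    member = _membership_per_sample(truth, n_timepoints, tr_seconds, window_spec)
    K = truth.assignments.n_communities
    n = truth.assignments.n_regions
    latents = _band_limited(rng, K, n_timepoints, tr_seconds, band)
    noise = _band_limited(rng, n, n_timepoints, tr_seconds, band)
    rho = truth.coupling
    t_idx = np.arange(n_timepoints)
    signals = np.sqrt(rho) * latents[member - 1, t_idx[None, :]] + np.sqrt(1.0 - rho) * noise
    return ParcellatedSeries(subject_id, signals, tr_seconds,
                             list(truth.assignments.region_ids))


def planted_metric_oracle(truth: PlantedTruth, atlas: AtlasLabels | None = None,
                          promiscuity_denominator: int | None = None) -> ReconfigMetrics:
    """Exact reconfiguration metrics of the ground-truth assignments."""
    return compute_metrics(truth.assignments, atlas=atlas,
                           promiscuity_denominator=promiscuity_denominator)


# ---------------------------------------------------------------------------
# cohort generation

#: Fatigue scale templates (mean, SD, maximum) per group — patient values
#: substantially above controls, as in the clinical population modelled.
FATIGUE_TEMPLATES = {
    "pwMS": {"fatigue_total": (50.3, 18.9, 100.0), "fatigue_motor": (25.9, 10.5, 50.0),
             "fatigue_cognitive": (24.4, 9.7, 50.0)},
    "HC": {"fatigue_total": (35.8, 10.1, 100.0), "fatigue_motor": (17.3, 5.2, 50.0),
           "fatigue_cognitive": (18.5, 5.4, 50.0)},
}

DMT_PROBS = np.array([37, 52, 9, 9, 15, 6, 13, 8, 6], dtype=float) / 155.0

EDSS_LEVELS = np.array([0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5])
EDSS_WEIGHTS = np.array([20, 25, 15, 10, 8, 6, 5, 3, 2, 2, 1.5, 1, 0.5])


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition template for a synthetic two-group cohort.

    ``effects`` maps a reconfiguration metric (by name) to its standardized
    association with each fatigue scale in the patient group; controls get
    no metric dependence.  The default plants the disjointedness–fatigue
    associations (0.24 total, 0.28 motor, 0.18 cognitive) that motivate the
    analysis.
    """

    n_pwms: int = 155
    n_hc: int = 48
    effects: dict = field(default_factory=lambda: {
        "disjointedness": {"fatigue_total": 0.24, "fatigue_motor": 0.28,
                           "fatigue_cognitive": 0.18},
    })
    coupling: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_pwms < 2 or self.n_hc < 2:
            raise ValueError("need at least 2 subjects per group")
        for metric, per_scale in self.effects.items():
            if metric not in METRIC_NAMES:
                raise ValueError(f"unknown metric {metric!r}")
            for scale, e in per_scale.items():
                if abs(e) >= 1.0:
                    raise ValueError(f"unattainable effect size {e} for {metric}->{scale}")
        for scale in {s for per in self.effects.values() for s in per}:
            total = sum(per.get(scale, 0.0) ** 2 for per in self.effects.values())
            if total >= 1.0:
                raise ValueError(f"combined effects on {scale} have total variance >= 1")


@dataclass
class CohortData:
    """Everything a pipeline run needs, plus the ground truth to score it."""

    series: dict          # subject_id -> ParcellatedSeries (empty if not built)
    phenotypes: pd.DataFrame
    truths: dict          # subject_id -> PlantedTruth
    planted: pd.DataFrame  # subject-level planted global metrics
    atlas: AtlasLabels


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(spec: CohortSpec, n_regions: int = 200, n_windows: int | None = None,
                    n_communities: int = 8, n_timepoints: int = 300,
                    tr_seconds: float = 1.0, window_spec: WindowSpec = WindowSpec(),
                    make_series: bool = True) -> CohortData:
    """Simulate a full two-group cohort, fully determined by ``spec.seed``.

    Per-subject switching intensities are drawn heterogeneously so the
    planted reconfiguration metrics vary across subjects; in the patient
    group each fatigue scale is generated as a linear function of the
    standardized planted metrics at the declared effect sizes plus
    independent noise, then clipped to the scale range.  ``make_series=False``
    skips signal synthesis when only phenotypes/truths are needed.
    """
    if n_windows is None:
        n_windows = len(make_windows(n_timepoints, tr_seconds, window_spec))
    master = np.random.default_rng(spec.seed)
    atlas = default_atlas(n_regions, n_communities)
    subjects = [f"MS{i + 1:03d}" for i in range(spec.n_pwms)] + \
               [f"HC{i + 1:03d}" for i in range(spec.n_hc)]
    groups = ["pwMS"] * spec.n_pwms + ["HC"] * spec.n_hc

    truths, series, planted_rows = {}, {}, []
    subject_rngs = master.spawn(len(subjects))
    for sid, rng in zip(subjects, subject_rngs):
        truth_seed = int(rng.integers(0, 2 ** 31 - 1))
        truth = make_planted_truth(
            truth_seed, n_regions=n_regions, n_windows=n_windows,
            n_communities=n_communities, atlas=atlas,
            n_disjoint_movers=int(rng.integers(10, 51)),
            n_cohesive_groups=int(rng.integers(2, 11)),
            max_mean_extra=float(rng.uniform(2.0, 10.0)),
            coupling=spec.coupling)
        truths[sid] = truth
        oracle = planted_metric_oracle(truth, atlas=atlas)
        planted_rows.append({"subject_id": sid,
                             **{m: oracle.global_means[m] for m in METRIC_NAMES}})
        if make_series:
            series[sid] = generate_subject(truth, subject_id=sid,
                                           n_timepoints=n_timepoints,
                                           tr_seconds=tr_seconds,
                                           window_spec=window_spec, seed=rng)
    planted = pd.DataFrame(planted_rows).set_index("subject_id")

    pheno = _generate_phenotypes(master, subjects, groups, planted, spec)
    return CohortData(series, pheno, truths, planted, atlas)


def _generate_phenotypes(rng, subjects, groups, planted, spec: CohortSpec) -> pd.DataFrame:
    groups = np.asarray(groups)
    n = len(subjects)
    is_ms = groups == "pwMS"
    df = pd.DataFrame(index=pd.Index(subjects, name="subject_id"))
    df["group"] = groups
    df["age"] = np.clip(np.where(is_ms, rng.normal(39, 10, n), rng.normal(33, 10, n)), 18, 75).round(0)
    df["sex"] = np.where(rng.uniform(size=n) < np.where(is_ms, 0.619, 0.708), 1, 0)
    df["education"] = np.clip(np.where(is_ms, rng.normal(14, 3, n), rng.normal(17, 3, n)), 8, 25).round(0)

    df["edss"] = np.where(is_ms, rng.choice(EDSS_LEVELS, size=n, p=EDSS_WEIGHTS / EDSS_WEIGHTS.sum()), np.nan)
    df["disease_duration"] = np.where(is_ms, np.abs(rng.normal(10, 8, n)).round(1), np.nan)
    dmt = rng.choice(np.array(DMT_CATEGORIES, dtype=object), size=n, p=DMT_PROBS)
    df["dmt_category"] = np.where(is_ms, dmt, None)
    df["nbv"] = np.where(is_ms, rng.normal(1512.1, 79.2, n), rng.normal(1572.9, 58.7, n)).round(1)
    df["t2_ll"] = np.where(is_ms, np.exp(rng.normal(np.log(3.5), 0.6, n)).round(2), np.nan)

    # fatigue: patients get the declared metric dependence, controls pure noise
    scales = sorted({s for per in spec.effects.values() for s in per} |
                    set(FATIGUE_TEMPLATES["pwMS"]))
    z_metrics = {m: np.zeros(n) for m in spec.effects}
    for m in spec.effects:
        z = _zscore(planted.loc[df.index[is_ms], m].to_numpy())
        z_metrics[m][is_ms] = z
    for scale in scales:
        eff = {m: per.get(scale, 0.0) for m, per in spec.effects.items()}
        resid_sd = np.sqrt(max(0.0, 1.0 - sum(e ** 2 for e in eff.values())))
        eps = rng.standard_normal(n)
        vals = np.empty(n)
        for grp in ("pwMS", "HC"):
            mu, sd, hi = FATIGUE_TEMPLATES[grp][scale]
            mask = groups == grp
            structured = np.zeros(mask.sum())
            if grp == "pwMS":
                structured = sum(e * z_metrics[m][mask] for m, e in eff.items())
                vals[mask] = mu + sd * (structured + resid_sd * eps[mask])
            else:
                vals[mask] = mu + sd * eps[mask]
            vals[mask] = np.clip(vals[mask], 0.0, hi)
        df[scale] = vals.round(1)
    return df
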