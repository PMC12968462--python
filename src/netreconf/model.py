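"""Top-level modelling interface: ReconfigurationModel → fit → Results.

``ReconfigurationModel`` bundles the data (parcellated series, atlas,
optional coverage and phenotypes) with the analysis configuration; ``fit()``
runs windowing → per-window community detection → reconfiguration metrics
for every subject, optionally the surrogate null, and the group statistics,
returning a :class:`ReconfigurationResults` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netreconf.communities import detect_all
from netreconf.io import AtlasLabels, ParcellatedSeries, exclude_low_coverage
from netreconf.metrics import METRIC_NAMES, compute_metrics, subject_summary
from netreconf.nulls import SurrogateSpec, build_null, null_adjusted_group_test
from netreconf.stats import correlate_metrics_fatigue, group_comparison_ancova
from netreconf.windows import WindowSpec, windowed_correlation


class ReconfigurationModel:
    """Time-varying reconfiguration analysis over a set of subjects.

    Parameters
    ----------
    series : dict or iterable of ParcellatedSeries
        The subjects' parcellated signal matrices.
    atlas : AtlasLabels
        Literature-based network membership used to seed detection and to
        aggregate node metrics per network.
    phenotypes : DataFrame, optional
        Subject table (group, fatigue scales, covariates) for the group
        statistics; statistics are skipped when absent.
    coverage : DataFrame, optional
        Subjects × regions voxel-coverage fractions; regions failing the
        coverage rule are excluded from every subject before analysis.
    """

    def __init__(self, series, atlas: AtlasLabels, phenotypes: pd.DataFrame | None = None,
                 coverage: pd.DataFrame | None = None,
                 window_spec: WindowSpec = WindowSpec(), n_communities: int = 8,
                 max_iterations: int = 1000,
                 promiscuity_denominator: int | None = None,
                 coverage_threshold: float = 0.30, subject_fraction: float = 0.10):
        if isinstance(series, dict):
            self.series = dict(series)
        else:
            self.series = {s.subject_id: s for s in series}
        if not self.series:
            raise ValueError("no subjects provided")
        self.atlas = atlas
        self.phenotypes = phenotypes
        self.window_spec = window_spec
        self.n_communities = n_communities
        self.max_iterations = max_iterations
        self.promiscuity_denominator = promiscuity_denominator

        self.retained_regions = None
        if coverage is not None:
            retained = set(exclude_low_coverage(coverage, coverage_threshold, subject_fraction))
            self.retained_regions = [r for r in next(iter(self.series.values())).region_ids
                                     if r in retained]
            self.series = {sid: _subset_regions(s, self.retained_regions)
                           for sid, s in self.series.items()}

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "ReconfigurationModel":
        """Build directly from a simulated :class:`~netreconf.simulate.CohortData`."""
        return cls(cohort.series, cohort.atlas, phenotypes=cohort.phenotypes, **kwargs)

    def fit(self, null_spec: SurrogateSpec | None = None,
            family_size: int | None = None,
            compute_statistics: bool = True) -> "ReconfigurationResults":
        assignments, metrics, traces, rows = {}, {}, {}, []
        for sid, s in self.series.items():
            wc = windowed_correlation(s, self.window_spec)
            am, tr = detect_all(wc, self.atlas, n_communities=self.n_communities,
                                max_iterations=self.max_iterations, return_traces=True)
            assignments[sid] = am
            traces[sid] = tr
            metrics[sid] = compute_metrics(am, atlas=self.atlas,
                                           promiscuity_denominator=self.promiscuity_denominator)
            rows.append(subject_summary(metrics[sid], sid))
        summaries = pd.concat(rows)

        null_summaries = None
        if null_spec is not None:
            null_rows = []
            for k, (sid, s) in enumerate(self.series.items()):
                sub_spec = SurrogateSpec(null_spec.n_runs, null_spec.mode,
                                         null_spec.phase_mode,
                                         seed=int(np.random.default_rng(
                                             [null_spec.seed, k]).integers(2 ** 31 - 1)))
                nm = build_null(s, sub_spec, window_spec=self.window_spec,
                                atlas=self.atlas, n_communities=self.n_communities,
                                max_iterations=self.max_iterations,
                                promiscuity_denominator=self.promiscuity_denominator)
                null_rows.append(subject_summary(nm, sid))
            null_summaries = pd.concat(null_rows)

        correlations = ancova = null_adjusted = None
        if compute_statistics and self.phenotypes is not None:
            correlations = correlate_metrics_fatigue(summaries, self.phenotypes,
                                                     family_size=family_size)
            if self.phenotypes["group"].nunique() >= 2:
                ancova = group_comparison_ancova(summaries, self.phenotypes,
                                                 family_size=family_size)
                if null_summaries is not None:
                    null_adjusted = null_adjusted_group_test(
                        summaries, null_summaries, self.phenotypes,
                        family_size=family_size)

        return ReconfigurationResults(
            model=self, assignments=assignments, metrics=metrics, traces=traces,
            summaries=summaries, null_summaries=null_summaries,
            correlations=correlations, ancova=ancova, null_adjusted=null_adjusted)


def _subset_regions(series: ParcellatedSeries, retained) -> ParcellatedSeries:
    idx = [series.region_ids.index(r) for r in retained]
    return ParcellatedSeries(series.subject_id, series.signals[idx],
                             series.tr_seconds, [series.region_ids[i] for i in idx])


@dataclass
class ReconfigurationResults:
    """Fitted per-subject assignments and metrics plus the group statistics."""

    model: ReconfigurationModel
    assignments: dict
    metrics: dict
    traces: dict
    summaries: pd.DataFrame
    null_summaries: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    ancova: pd.DataFrame | None = None
    null_adjusted: pd.DataFrame | None = None
    _extra: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.assignments)

    def global_means(self, group: str | None = None) -> pd.DataFrame:
        """Mean (SD) of the global metrics, optionally within one group."""
        df = self.summaries[[f"global_{m}" for m in METRIC_NAMES]]
        if group is not None and self.model.phenotypes is not None:
            keep = self.model.phenotypes["group"].reindex(df.index) == group
            df = df[keep]
        return pd.DataFrame({"mean": df.mean(), "sd": df.std()})

    def summary(self) -> str:
        am = next(iter(self.assignments.values()))
        lines = [
            "Time-varying network reconfiguration".center(70),
            "=" * 70,
            f"Subjects: {self.n_subjects}    Regions: {am.n_regions}    "
            f"Windows: {am.n_windows}    Communities: {am.n_communities}",
            "-" * 70,
            "Global metrics, mean (SD) across subjects:",
        ]
        gm = self.global_means()
        for m in METRIC_NAMES:
            row = gm.loc[f"global_{m}"]
            lines.append(f"  {m:<16s} {row['mean']:.3f} ({row['sd']:.3f})")
        if self.ancova is not None:
            lines.append("-" * 70)
            lines.append("Group comparison (ANCOVA: metric ~ group + age + sex + education):")
            for metric, row in self.ancova.iterrows():
                lines.append(f"  {metric:<24s} F={row['F']:.3f}  p_adj={row['p_adj']:.3f}")
        if self.correlations is not None:
            sig = self.correlations[self.correlations["p_adj"] < 0.05]
            lines.append("-" * 70)
            lines.append(f"Metric–fatigue correlations: {len(self.correlations)} tested, "
                         f"{len(sig)} significant after Bonferroni")
            for _, row in sig.iterrows():
                lines.append(f"  [{row['group']}] {row['metric']} ~ {row['fatigue_scale']}: "
                             f"r={row['r']:.2f}, p_adj={row['p_adj']:.3f}")
        lines.append("=" * 70)
        return "\n".join(lines)
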