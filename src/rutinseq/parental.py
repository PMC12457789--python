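"""Partition of F1 seed rutin content into maternal and pollen-parent effects.

The model treats the F1 group mean as a mixture of the parental means,

    F1 = m * Pm + (1 - m) * Pp,

so the maternal effect is m = (F1 - Pp) / (Pm - Pp) and the pollen-parent
(xenia) effect is 1 - m.  The mid-parent value MP = (Pm + Pp) / 2 is the
m = 1/2 benchmark.  m is reported as computed, without clamping: values
outside [0, 1] indicate over-dominance of one parent and are flagged.

Group means are compared by Fisher's Least Significant Difference test:
a one-way ANOVA pools the error variance over all groups grown in the same
plot, and each pair is compared with a t statistic on the pooled variance
(no multiplicity adjustment, by construction of the LSD procedure).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pathway import classify_rutin_group
from .types import (
    MISSING,
    CrossSpec,
    EffectResult,
    LineSpec,
    RunConfig,
    SeedRutinRecord,
    UndefinedEffectError,
    round_half_away,
)

logger = logging.getLogger("rutinseq")

__all__ = [
    "mid_parent_value", "maternal_effect", "pollen_effect", "lsd_test",
    "group_mean_effects", "compute_effects", "star_code",
    "ParentalEffectsModel", "ParentalEffectsResults", "LsdResult",
]


def mid_parent_value(pm_mean: float, pp_mean: float) -> float:
    """Mid-parent value MP = (Pm + Pp) / 2."""
    return 0.5 * (pm_mean + pp_mean)


def maternal_effect(f1_mean: float, pm_mean: float, pp_mean: float) -> float:
    """Maternal effect m = (F1 - Pp) / (Pm - Pp), unclamped.

    Raises :class:`UndefinedEffectError` when the parental means coincide.
    """
    if pm_mean == pp_mean:
        raise UndefinedEffectError(
            f"maternal effect undefined: Pm == Pp == {pm_mean}"
        )
    return (f1_mean - pp_mean) / (pm_mean - pp_mean)


def pollen_effect(m: float) -> float:
    """Pollen-parent effect, the exact complement 1 - m."""
    return 1.0 - m


def star_code(p: float, decimals: int = 2) -> str:
    """Significance stars: ***<0.001, **<0.01, *<0.05, else p printed."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return f"{round_half_away(p, decimals):.{decimals}f}"


@dataclass
class LsdResult:
    """Pairwise p-values from Fisher's LSD on one set of groups."""

    labels: list[str]
    means: dict[str, float]
    ns: dict[str, int]
    mse: float
    df: int
    p_values: dict[frozenset, float]

    def p(self, a: str, b: str) -> float:
        return self.p_values[frozenset((a, b))]

    def stars(self, a: str, b: str, decimals: int = 2) -> str:
        return star_code(self.p(a, b), decimals)


def lsd_test(groups: Sequence[tuple[str, Sequence[float]]]) -> LsdResult:
    """Fisher's LSD: pooled one-way-ANOVA error variance, pairwise t tests.

    ``MSE = SSE / (N - k)`` over the k groups; for each pair,
    ``t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j))`` with N - k
    degrees of freedom, two-sided.  Degenerate inputs (all values identical
    within every group, MSE = 0) yield p = 1 for equal means and p = 0
    otherwise, with a warning.
    """
    if len(groups) < 2:
        raise ValueError("lsd_test needs at least 2 groups")
    labels = [g[0] for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    arrays = {lab: np.asarray(vals, dtype=float) for lab, vals in groups}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least 2 values")

    n_total = sum(a.size for a in arrays.values())
    k = len(arrays)
    df = n_total - k
    sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays.values())
    mse = sse / df
    means = {lab: float(a.mean()) for lab, a in arrays.items()}
    ns = {lab: int(a.size) for lab, a in arrays.items()}

    p_values: dict[frozenset, float] = {}
    degenerate = mse == 0.0
    if degenerate:
        warnings.warn("degenerate LSD: zero pooled error variance", stacklevel=2)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if degenerate:
                p = 1.0 if means[a] == means[b] else 0.0
            else:
                se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
                t = (means[a] - means[b]) / se
                p = 2.0 * float(stats.t.sf(abs(t), df))
            p_values[frozenset((a, b))] = p
    return LsdResult(labels=labels, means=means, ns=ns, mse=mse, df=df,
                     p_values=p_values)


def group_mean_effects(effects: Sequence[float]) -> float:
    """Arithmetic mean of effect values (the block-average rows)."""
    if len(effects) == 0:
        raise ValueError("empty effect list")
    return float(np.mean(effects))


def _group_values(records: Iterable[SeedRutinRecord]) -> dict[str, np.ndarray]:
    by_line: dict[str, list[float]] = {}
    for r in records:
        by_line.setdefault(r.line, []).append(r.rutin)
    return {k: np.asarray(v, dtype=float) for k, v in by_line.items()}


def compute_effects(
    measurements: Iterable[SeedRutinRecord],
    line_specs: Sequence[LineSpec],
    crosses: Sequence[CrossSpec],
    config: RunConfig | None = None,
) -> list[EffectResult]:
    """Per-cross effect partition with LSD significance.

    Group means come from the per-seed measurements (F1 seeds carry the
    cross_id as their line label).  The LSD runs once per plot over every
    group grown there (both parent lines and every F1 of the plot) with
    per-seed values as replicates; ``config.lsd_scope='cross'`` restricts it
    to the (Pm, F1, Pp) triple of each cross.  Effects are computed from
    unrounded means; rounding happens only at report time.
    """
    config = config or RunConfig()
    values = _group_values(measurements)
    results: list[EffectResult] = []

    # one pooled LSD per plot (or per cross when so configured)
    lsd_cache: dict[str, LsdResult] = {}

    def plot_lsd(cross: CrossSpec) -> LsdResult | None:
        if config.lsd_scope == "cross":
            key = cross.cross_id
            members = [cross.maternal, cross.cross_id, cross.pollen]
        else:
            key = cross.plot_group
            plot_crosses = [c for c in crosses if c.plot_group == cross.plot_group]
            members = []
            for c in plot_crosses:
                for g in (c.maternal, c.pollen, c.cross_id):
                    if g not in members:
                        members.append(g)
        if key not in lsd_cache:
            groups = [(g, values[g]) for g in members if g in values]
            if len(groups) < 2 or any(len(v) < 2 for _, v in groups):
                return None
            lsd_cache[key] = lsd_test(groups)
        return lsd_cache[key]

    for cross in crosses:
        needed = [cross.maternal, cross.pollen, cross.cross_id]
        absent = [g for g in needed if g not in values]
        if absent:
            logger.warning("cross %s skipped: no measurements for %s",
                           cross.cross_id, absent)
            continue
        pm = float(values[cross.maternal].mean())
        pp = float(values[cross.pollen].mean())
        f1 = float(values[cross.cross_id].mean())
        f1_sd = float(values[cross.cross_id].std(ddof=1))
        m = maternal_effect(f1, pm, pp)
        lsd = plot_lsd(cross)
        p_pm = p_pp = stars_pm = stars_pp = None
        if lsd is not None:
            p_pm = lsd.p(cross.maternal, cross.cross_id)
            p_pp = lsd.p(cross.pollen, cross.cross_id)
            stars_pm = star_code(p_pm, config.rounding_decimals)
            stars_pp = star_code(p_pp, config.rounding_decimals)
        results.append(EffectResult(
            cross_id=cross.cross_id,
            pm_mean=pm, pp_mean=pp, f1_mean=f1, f1_sd=f1_sd,
            mp=mid_parent_value(pm, pp),
            m=m, pollen_effect=pollen_effect(m),
            p_pm_vs_f1=p_pm, p_pp_vs_f1=p_pp,
            stars_pm=stars_pm, stars_pp=stars_pp,
        ))
    logger.info("computed effects for %d/%d crosses", len(results), len(crosses))
    return results


class ParentalEffectsModel:
    """Maternal/pollen effect partition fitted to per-seed rutin data.

    Parameters
    ----------
    measurements
        Per-seed records; F1 seeds use the cross_id as line label.
    crosses
        Cross design (maternal, pollen, plot grouping).
    lines
        Optional line metadata; used to block crosses by the maternal
        parent's rutin group for the block-average rows.
    config
        Pipeline constants (rounding, LSD scope).
    """

    def __init__(self, measurements, crosses, lines=None, config=None):
        self.measurements = list(measurements)
        self.crosses = list(crosses)
        self.lines = list(lines) if lines else None
        self.config = config or RunConfig()

    @classmethod
    def from_files(cls, rutin_path, crosses_path, lines_path=None, config=None):
        from . import io
        return cls(
            io.read_rutin_table(rutin_path),
            io.read_crosses_table(crosses_path),
            io.read_lines_table(lines_path) if lines_path else None,
            config,
        )

    def fit(self) -> "ParentalEffectsResults":
        effects = compute_effects(self.measurements, self.lines or [],
                                  self.crosses, self.config)
        return ParentalEffectsResults(self, effects)


class ParentalEffectsResults:
    """Fitted effect partition: per-cross estimates and block averages."""

    def __init__(self, model: ParentalEffectsModel, effects: list[EffectResult]):
        self.model = model
        self.effects = effects

    def _maternal_block(self, cross: CrossSpec) -> str:
        if not self.model.lines:
            return "all"
        by_name = {l.name: l for l in self.model.lines}
        cfg = self.model.config
        spec = by_name.get(cross.maternal)
        if spec is None:
            return "all"
        return classify_rutin_group(spec.rutin_mean, cfg.group_low, cfg.group_high)

    def block_averages(self) -> dict[str, tuple[float, float]]:
        """Mean maternal and pollen effects per maternal-rutin-group block."""
        by_id = {c.cross_id: c for c in self.model.crosses}
        blocks: dict[str, list[EffectResult]] = {}
        for e in self.effects:
            blocks.setdefault(self._maternal_block(by_id[e.cross_id]), []).append(e)
        return {
            b: (group_mean_effects([e.m for e in es]),
                group_mean_effects([e.pollen_effect for e in es]))
            for b, es in blocks.items()
        }

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        nd = self.model.config.rounding_decimals
        rows = []
        for e in self.effects:
            row = {
                "cross_id": e.cross_id, "mp": e.mp, "f1_mean": e.f1_mean,
                "f1_sd": e.f1_sd, "sig_pm_vs_f1": e.stars_pm or MISSING,
                "sig_pp_vs_f1": e.stars_pp or MISSING,
                "maternal_effect": e.m, "pollen_effect": e.pollen_effect,
            }
            if rounded:
                for col in ("mp", "f1_mean", "f1_sd", "maternal_effect", "pollen_effect"):
                    row[col] = round_half_away(row[col], nd)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Report-style table: per-cross rows plus block-average rows."""
        nd = self.model.config.rounding_decimals
        df = self.to_frame(rounded=True)
        lines = ["Parental effects on F1 seed rutin content",
                 "=" * 63,
                 f"{'cross':<13}{'MP':>6}{'F1':>6}{'SD':>6}{'Pm vs F1':>10}"
                 f"{'Pp vs F1':>10}{'m':>6}{'1-m':>6}"]
        for _, r in df.iterrows():
            lines.append(
                f"{r.cross_id:<13}{r.mp:>6.2f}{r.f1_mean:>6.2f}{r.f1_sd:>6.2f}"
                f"{r.sig_pm_vs_f1:>10}{r.sig_pp_vs_f1:>10}"
                f"{r.maternal_effect:>6.2f}{r.pollen_effect:>6.2f}"
            )
        for block, (m_avg, p_avg) in self.block_averages().items():
            lines.append(
                f"{'avg(' + block + ')':<13}{'':>6}{'':>6}{'':>6}{'':>10}{'':>10}"
                f"{round_half_away(m_avg, nd):>6.2f}{round_half_away(p_avg, nd):>6.2f}"
            )
        lines.append("=" * 63)
        return "\n".join(lines)

    def plot_distributions(self, ax=None):
        """Boxplots of per-seed rutin by group (parents and F1s)."""
        import matplotlib.pyplot as plt

        values = _group_values(self.model.measurements)
        labels = list(values)
        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, len(labels)), 3))
        ax.boxplot([values[l] for l in labels], tick_labels=labels)
        ax.set_ylabel("rutin (mg/g)")
        return ax
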