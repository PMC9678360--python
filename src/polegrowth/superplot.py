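"""Super-plot statistics: replicate medians and paired one-way ANOVA.

A "super plot" avoids pseudo-replication in single-cell data: the hundreds
of per-cell measurements within one biological replicate are first reduced
to the replicate median, and inference runs on the replicate medians with
replicate as a pairing (blocking) factor — a balanced repeated-measures
one-way ANOVA across strains. For two strains the F statistic equals the
square of the paired t statistic on block-wise differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class BalanceError(ValueError):
    """The (strain, replicate) design is incomplete."""


@dataclass
class PairedContrast:
    """A k=2 repeated-measures contrast of one strain against the reference."""

    strain: str
    reference: str
    F: float
    df: tuple[int, int]
    p_value: float
    p_adjusted: float = math.nan


@dataclass
class SuperplotSummary:
    """Replicate medians plus the paired one-way ANOVA over strains."""

    medians: pd.DataFrame  # index = strain, columns = replicate
    k: int
    n: int
    F: float
    df_between: int
    df_error: int
    p_value: float
    degenerate: bool = False
    contrasts: list[PairedContrast] = field(default_factory=list)

    def report(self) -> str:
        lines = ["Super-plot summary", "==================", "", "Replicate medians:"]
        lines.append(self.medians.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append(
            f"Paired one-way ANOVA (replicate as block): "
            f"F({self.df_between}, {self.df_error}) = {self.F:.4f}, p = {self.p_value:.4g}"
            + ("  [degenerate: zero error variance]" if self.degenerate else "")
        )
        for c in self.contrasts:
            lines.append(
                f"  {c.strain} vs {c.reference}: F({c.df[0]}, {c.df[1]}) = {c.F:.4f}, "
                f"p = {c.p_value:.4g}, p_adj = {c.p_adjusted:.4g}"
            )
        return "\n".join(lines)


def replicate_medians(
    measurements: pd.DataFrame,
    value: str,
    strain: str = "strain",
    replicate: str = "replicate",
) -> pd.DataFrame:
    """Median of the per-cell values for every (strain, replicate) group.

    Requires a balanced design: every strain must appear in every replicate.
    Even-sized groups use the mean of the two central order statistics
    (the ordinary sample median).
    """
    strains = measurements[strain].unique()
    reps = measurements[replicate].unique()
    grouped = measurements.groupby([strain, replicate], sort=False)[value].median()
    missing = [
        (s, r) for s in strains for r in reps if (s, r) not in grouped.index
    ]
    if missing:
        raise BalanceError(f"missing (strain, replicate) groups: {missing}")
    table = grouped.unstack(replicate)
    return table.loc[strains, reps]


def _rm_anova(values: np.ndarray) -> tuple[float, int, int, float, bool]:
    """Balanced repeated-measures one-way ANOVA on a k x n value matrix."""
    k, n = values.shape
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_strain = float(n * ((values.mean(axis=1) - grand) ** 2).sum())
    ss_block = float(k * ((values.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_strain - ss_block
    df_b, df_e = k - 1, (k - 1) * (n - 1)
    if ss_error <= 1e-12 * max(ss_total, 1.0):
        if ss_strain <= 1e-12 * max(ss_total, 1.0):
            return 0.0, df_b, df_e, 1.0, ss_total > 0
        return math.inf, df_b, df_e, 0.0, True
    F = (ss_strain / df_b) / (ss_error / df_e)
    p = float(sps.f.sf(F, df_b, df_e))
    return F, df_b, df_e, p, False


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def paired_oneway_anova(
    medians: pd.DataFrame | np.ndarray,
    reference: str | None = None,
    adjust: str = "holm",
) -> SuperplotSummary:
    """Paired (repeated-measures) one-way ANOVA over a k-strain x n-replicate table.

    Rows are strains, columns replicates (blocks); the design must be
    balanced with k >= 2 strains and n >= 2 replicates. If ``reference`` is
    given, each other strain is additionally contrasted against it with a
    k=2 repeated-measures ANOVA, with the chosen multiple-comparison
    adjustment (``holm`` default, also ``bonferroni`` or ``none``).
    """
    if isinstance(medians, pd.DataFrame):
        table = medians
    else:
        arr = np.asarray(medians, dtype=float)
        table = pd.DataFrame(arr, index=[f"strain{i}" for i in range(arr.shape[0])])
    values = table.to_numpy(dtype=float)
    k, n = values.shape
    if k < 2 or n < 2:
        raise ValueError(f"need k >= 2 strains and n >= 2 replicates, got k={k}, n={n}")
    if not np.all(np.isfinite(values)):
        raise BalanceError("median table contains missing values; design must be balanced")
    F, df_b, df_e, p, degenerate = _rm_anova(values)
    contrasts: list[PairedContrast] = []
    if reference is not None:
        if reference not in table.index:
            raise ValueError(f"reference strain {reference!r} not in table")
        others = [s for s in table.index if s != reference]
        for s in others:
            sub = values[[table.index.get_loc(s), table.index.get_loc(reference)], :]
            Fc, db, de, pc, _ = _rm_anova(sub)
            contrasts.append(PairedContrast(s, reference, Fc, (db, de), pc))
        raw = [c.p_value for c in contrasts]
        if adjust == "holm":
            adj = holm_adjust(raw)
        elif adjust == "bonferroni":
            adj = [min(1.0, len(raw) * v) for v in raw]
        elif adjust == "none":
            adj = raw
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        for c, a in zip(contrasts, adj):
            c.p_adjusted = a
    return SuperplotSummary(
        medians=table,
        k=k,
        n=n,
        F=F,
        df_between=df_b,
        df_error=df_e,
        p_value=p,
        degenerate=degenerate,
        contrasts=contrasts,
    )


def superplot(
    measurements: pd.DataFrame,
    value: str,
    strain: str = "strain",
    replicate: str = "replicate",
    reference: str | None = None,
    adjust: str = "holm",
) -> SuperplotSummary:
    """Convenience: replicate medians followed by the paired one-way ANOVA."""
    table = replicate_medians(measurements, value, strain, replicate)
    return paired_oneway_anova(table, reference=reference, adjust=adjust)
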