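"""Count-table statistics: relative abundance, rarefaction, diversity, and
the per-strain T6SS-sensitivity statistic.

The central object is a :class:`CountTable`: a samples x strains matrix of
amplicon read counts (e.g. gyrB ASV counts collapsed to SynCom members)
plus per-sample metadata. Confrontation metadata carries the assay arm
(``WT`` — functional T6SS — vs ``dhcp`` — the Δhcp loss-of-function
control), the timepoint in hours, and a replicate identifier.

The sensitivity statistic for strain i is

    S_i = log2[ (RA_6h / RA_0h)_WT / (RA_6h / RA_0h)_dhcp ]

computed on replicate-mean relative abundances per arm x timepoint cell.
Negative S_i means the strain lost relative abundance specifically when the
attacker's T6SS was functional — T6SS-mediated depletion. A bootstrap over
replicates (resampling within each cell) provides a percentile confidence
interval and a sensitive/resistant/indeterminate call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARM_WT",
    "ARM_DHCP",
    "CountTable",
    "SensitivityScore",
    "to_relative_abundance",
    "rarefy",
    "alpha_diversity",
    "prevalence_filter",
    "sensitivity_score",
    "sensitivity_table",
    "cfu_detection_filter",
]

ARM_WT = "WT"
ARM_DHCP = "dhcp"

_META_COLS = ("arm", "timepoint_h", "replicate")


@dataclass
class CountTable:
    """Samples x strains counts with per-sample metadata.

    ``counts``: DataFrame indexed by sample id, one column per strain,
    non-negative values (integer reads, or floats after conversion to
    relative abundance). ``meta``: DataFrame indexed by the same sample
    ids; confrontation tables carry 'arm', 'timepoint_h', 'replicate'.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.counts.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.counts.index)
            if self.meta.isna().all(axis=1).any():
                raise ValueError("metadata missing for some samples")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def strains(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.meta.copy())


def to_relative_abundance(table: CountTable, pseudocount: float = 0.5,
                          expected: pd.DataFrame | None = None) -> CountTable:
    """Convert counts to relative abundances with targeted pseudocounts.

    ``RA_i = (c_i + pseudocount * z_i) / sum_j (c_j + pseudocount * z_j)``
    where ``z_i = 1`` only for strains expected in the sample's community
    design (``expected``: samples x strains boolean DataFrame; default all
    strains expected everywhere). Strains that cannot be present receive no
    pseudocount, so they keep RA exactly 0. Every row sums to 1.
    """
    counts = table.counts.astype(float)
    if expected is None:
        z = pd.DataFrame(1.0, index=counts.index, columns=counts.columns)
    else:
        z = expected.reindex(index=counts.index, columns=counts.columns).astype(float)
    adjusted = counts + pseudocount * z
    totals = adjusted.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s) after pseudocounting: {list(zero.index)}")
    ra = adjusted.div(totals, axis=0)
    return CountTable(ra, table.meta.copy())


def rarefy(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning. One subsample per sample (not an average), deterministic for a
    given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept_rows = []
    kept_idx = []
    for sample, row in table.counts.iterrows():
        total = int(row.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} < {depth} reads; dropped",
                stacklevel=2,
            )
            continue
        sub = rng.multivariate_hypergeometric(row.to_numpy().astype(int), depth)
        kept_rows.append(sub)
        kept_idx.append(sample)
    counts = pd.DataFrame(kept_rows, index=kept_idx, columns=table.counts.columns)
    counts.index.name = table.counts.index.name
    return CountTable(counts, table.meta.loc[kept_idx].copy())


def alpha_diversity(table: CountTable, metric: str = "shannon") -> pd.Series:
    """Per-sample richness, Shannon H (natural log), or Pielou evenness.

    Pielou's J = H / ln(richness) is reported as NaN when richness <= 1
    (the evenness of a single-strain sample is undefined).
    """
    counts = table.counts.to_numpy(dtype=float)
    richness = (counts > 0).sum(axis=1).astype(float)
    if metric == "richness":
        values = richness
    elif metric in ("shannon", "pielou"):
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(totals > 0, counts / totals, 0.0)
            h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        if metric == "shannon":
            values = h
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                values = np.where(richness > 1, h / np.log(richness), np.nan)
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return pd.Series(values, index=table.counts.index, name=metric)


def prevalence_filter(table: CountTable, min_prevalence: float = 0.2) -> CountTable:
    """Keep strains present (count > 0) in >= ``min_prevalence`` of samples.

    Prevalence is computed on the raw table, before any pseudocounting; the
    boundary case (prevalence exactly at the threshold) is kept. The result
    may have zero strains.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index
    return CountTable(table.counts[keep].copy(), table.meta.copy())


@dataclass
class SensitivityScore:
    """Per-strain log2 T6SS-sensitivity with bootstrap CI and call."""

    strain: str
    s: float
    ci_low: float
    ci_high: float
    n_boot: int
    status: str  # sensitive | resistant | indeterminate | undefined

    def as_dict(self) -> dict:
        return {
            "strain": self.strain, "S": self.s, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "n_boot": self.n_boot, "status": self.status,
        }


def _cell_values(ra: CountTable, strain: str, arm: str, timepoint: float) -> np.ndarray:
    meta = ra.meta
    mask = (meta["arm"] == arm) & (meta["timepoint_h"] == timepoint)
    return ra.counts.loc[mask.to_numpy(), strain].to_numpy(dtype=float)


def _log2_ratio_of_means(cells: list[np.ndarray]) -> float:
    # computed as a difference of per-arm log ratios so that swapping the
    # arm labels negates S exactly (bitwise) in IEEE arithmetic
    wt0, wt6, dh0, dh6 = (c.mean() for c in cells)
    return float(np.log2(wt6 / wt0) - np.log2(dh6 / dh0))


def sensitivity_score(ra: CountTable, strain: str, n_boot: int = 2000,
                      seed: int = 0, timepoints: tuple[float, float] = (0.0, 6.0),
                      arms: tuple[str, str] = (ARM_WT, ARM_DHCP)) -> SensitivityScore:
    """The log2 T6SS-sensitivity statistic for one strain.

    ``ra`` is a relative-abundance table (see :func:`to_relative_abundance`)
    whose metadata contains both arms at both timepoints. S is computed on
    replicate means per arm x timepoint cell; the percentile bootstrap
    resamples replicates within each cell independently (the design is
    unpaired across arms). Status: ``sensitive`` if the CI lies entirely
    below 0, ``resistant`` if entirely above, ``indeterminate`` otherwise,
    and ``undefined`` (S = NaN) if the strain has zero mean RA in any cell.
    """
    t0, t1 = timepoints
    arm_wt, arm_ctrl = arms
    cells = [
        _cell_values(ra, strain, arm_wt, t0),
        _cell_values(ra, strain, arm_wt, t1),
        _cell_values(ra, strain, arm_ctrl, t0),
        _cell_values(ra, strain, arm_ctrl, t1),
    ]
    if any(len(c) == 0 for c in cells):
        raise ValueError(
            f"strain {strain!r}: need both arms at t={t0} and t={t1} h"
        )
    if any(c.mean() == 0 for c in cells):
        return SensitivityScore(strain, float("nan"), float("nan"),
                                float("nan"), n_boot, "undefined")

    s = _log2_ratio_of_means(cells)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        resampled = [rng.choice(c, size=len(c), replace=True) for c in cells]
        if any(r.mean() == 0 for r in resampled):
            boot[b] = np.nan
        else:
            boot[b] = _log2_ratio_of_means(resampled)
    boot = boot[np.isfinite(boot)]
    if len(boot):
        ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    else:
        ci_low = ci_high = float("nan")
    # the point estimate is kept inside the reported interval
    ci_low = min(ci_low, s)
    ci_high = max(ci_high, s)
    if ci_high < 0:
        status = "sensitive"
    elif ci_low > 0:
        status = "resistant"
    else:
        status = "indeterminate"
    return SensitivityScore(strain, s, float(ci_low), float(ci_high), n_boot, status)


def sensitivity_table(ra: CountTable, strains=None, n_boot: int = 2000,
                      seed: int = 0, focal: str | None = None) -> pd.DataFrame:
    """Sensitivity scores for every (non-focal) strain, as a DataFrame."""
    if strains is None:
        strains = [s for s in ra.strains if s != focal]
    rows = []
    for i, strain in enumerate(strains):
        score = sensitivity_score(ra, strain, n_boot=n_boot, seed=seed + i)
        rows.append(score.as_dict())
    return pd.DataFrame(rows).set_index("strain")


def cfu_detection_filter(cfu: pd.DataFrame, limit: float = 1e3,
                         value_col: str = "cfu") -> pd.DataFrame:
    """Drop CFU records below the plating detection limit.

    Records with CFU >= ``limit`` are kept (the boundary value is
    detectable); records below are removed, mirroring a detection threshold
    of 10^3 CFU per individual.
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    return cfu[cfu[value_col] >= limit].copy()
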