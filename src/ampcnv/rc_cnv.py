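"""Post-sequencing read-count screening.

Each sequencing run yields, per sample, a read count for every amplicon.
Two statistics drive CNV screening:

* **within-plex frequency** -- an amplicon's count divided by the total
  count of its plex in that sample.  This removes per-plex loading and
  library-size effects; a heterozygous deletion halves the affected
  amplicons' frequencies (and slightly inflates the rest of the plex).
  Each amplicon's run-level mean and CI99% (mean +/- 2.576 sd across the
  run's samples) form the acceptance band; samples are screened
  leave-one-out so an aberrant sample cannot widen its own band.
* **global gene ratio** -- per plex, the ratio of summed gene-1 counts to
  summed gene-2 counts, averaged over plexes.  A whole-gene event doubles
  or halves this ratio; the cohort's mean +/- sd provides the reference
  range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ampcnv.panel import PanelDesign
from ampcnv.states import RcFlag

#: two-sided z quantile for a 99% normal interval
Z99 = 2.576


@dataclass
class ReadCountMatrix:
    """Samples x amplicons non-negative integer read counts."""

    counts: pd.DataFrame  # index: sample ids, columns: amplicon ids
    panel: PanelDesign

    def __post_init__(self) -> None:
        panel_ids = [a.id for a in self.panel.amplicons]
        have = set(self.counts.columns)
        want = set(panel_ids)
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise ValueError(
                f"count columns do not match panel amplicons "
                f"(missing {missing[:5]}, extra {extra[:5]})"
            )
        self.counts = self.counts[panel_ids]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("sample").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, panel: PanelDesign) -> "ReadCountMatrix":
        """Read counts from wide (sample x amplicon) or tidy long format."""
        df = pd.read_csv(path, sep="\t")
        if {"sample", "amplicon_id", "count"}.issubset(df.columns):
            wide = df.pivot(index="sample", columns="amplicon_id", values="count")
        else:
            wide = df.set_index(df.columns[0])
        wide.index.name = None
        wide.columns.name = None
        return cls(counts=wide.astype(int), panel=panel)


@dataclass
class AmpliconRunStats:
    """Per-amplicon frequency mean, sd and CI99% over a run's samples."""

    stats: pd.DataFrame  # index: amplicon ids; columns: mean, sd, ci99_low, ci99_high
    n_baseline: int
    excluded_sample: Optional[str] = None

    def to_tsv(self, path: str | Path) -> None:
        self.stats.rename_axis("amplicon_id").to_csv(path, sep="\t")


@dataclass
class GeneRatioResult:
    """Per-sample per-plex and global gene-1/gene-2 count ratios."""

    per_plex: pd.DataFrame      # index: samples, columns: plexes
    global_ratio: pd.Series     # index: samples
    cohort_mean: float
    cohort_sd: float
    flagged: pd.Series          # bool per sample (leave-one-out gate)
    sd_multiplier: float

    def to_json_dict(self) -> dict:
        return {
            "global_ratio": self.global_ratio.round(6).to_dict(),
            "cohort_mean": round(self.cohort_mean, 6),
            "cohort_sd": round(self.cohort_sd, 6),
            "sd_multiplier": self.sd_multiplier,
            "flagged": {k: bool(v) for k, v in self.flagged.items()},
        }


def _plex_map(panel: PanelDesign) -> dict[str, list[str]]:
    return {
        plex: [a.id for a in panel.amplicons_in_plex(plex)]
        for plex in panel.plexes
    }


def rc_frequency(matrix: ReadCountMatrix) -> pd.DataFrame:
    """Within-plex frequency table (same shape as the count matrix).

    frequency = count / (sum of counts over the amplicon's plex in that
    sample); frequencies within a plex sum to 1 per sample.
    """
    counts = matrix.counts
    freq = counts.astype(float).copy()
    for plex, cols in _plex_map(matrix.panel).items():
        totals = counts[cols].sum(axis=1)
        zero = totals[totals == 0]
        if not zero.empty:
            raise ValueError(
                f"zero total read count in plex {plex!r} for sample "
                f"{zero.index[0]!r}"
            )
        freq[cols] = counts[cols].div(totals, axis=0)
    return freq


def run_ci99(
    matrix: ReadCountMatrix,
    exclude_sample: Optional[str] = None,
    z: float = Z99,
) -> AmpliconRunStats:
    """Per-amplicon frequency mean and CI99% over the run's samples.

    ``exclude_sample`` removes the queried sample from its own baseline
    (leave-one-out); at least 3 baseline samples are required.
    """
    freq = rc_frequency(matrix)
    if exclude_sample is not None:
        if exclude_sample not in freq.index:
            raise KeyError(f"sample {exclude_sample!r} not in matrix")
        freq = freq.drop(index=exclude_sample)
    n = len(freq)
    if n < 3:
        raise ValueError(f"need >= 3 baseline samples, have {n}")
    mean = freq.mean(axis=0)
    sd = freq.std(axis=0, ddof=1)
    stats = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "ci99_low": mean - z * sd,
            "ci99_high": mean + z * sd,
        }
    )
    return AmpliconRunStats(stats=stats, n_baseline=n, excluded_sample=exclude_sample)


def flag_rc_outliers(
    sample_freq: pd.Series,
    stats: AmpliconRunStats,
    panel: Optional[PanelDesign] = None,
) -> dict[str, RcFlag]:
    """Flag a sample's frequencies against the run CI99% (closed interval).

    With ``panel`` given, the sample's frequencies are first recentered
    per plex by the median of (baseline mean / sample frequency) -- the
    same median-anchor logic as the fragment-analysis stage.  Within-plex
    frequencies are compositional: a large CNV shifts *every other*
    amplicon's frequency in its plex, so raw comparison flags innocent
    neighbours.  The median anchor absorbs that shift; when the affected
    amplicons are the plex majority the anchor instead lands on them and
    the *unaffected* gene is flagged -- either way one gene's pattern
    surfaces.  Without ``panel`` frequencies are compared as-is.
    """
    freq = sample_freq.astype(float).copy()
    if panel is not None:
        for plex, cols in _plex_map(panel).items():
            ratios = [
                stats.stats.loc[a, "mean"] / freq[a]
                for a in cols
                if a in freq.index and freq[a] > 0
            ]
            if ratios:
                freq[ [c for c in cols if c in freq.index] ] *= float(
                    np.median(ratios)
                )
    flags: dict[str, RcFlag] = {}
    for aid, f in freq.items():
        if aid not in stats.stats.index:
            raise KeyError(f"amplicon {aid!r} absent from run statistics")
        row = stats.stats.loc[aid]
        if f < row["ci99_low"]:
            flags[aid] = RcFlag.LOW
        elif f > row["ci99_high"]:
            flags[aid] = RcFlag.HIGH
        else:
            flags[aid] = RcFlag.IN_CI
    return flags


def global_gene_ratio(
    matrix: ReadCountMatrix,
    sd_multiplier: float = 2.0,
    pooled: bool = False,
) -> GeneRatioResult:
    """Global gene-1/gene-2 read-count ratio per sample.

    Per-plex ratio = sum(gene-1 counts) / sum(gene-2 counts); the global
    ratio is the unweighted mean of per-plex ratios (``pooled=True``
    instead sums counts over all plexes before dividing).  Each sample is
    gated against the mean +/- ``sd_multiplier``*sd of the *other*
    samples' global ratios.
    """
    panel = matrix.panel
    g1, g2 = panel.gene_labels
    counts = matrix.counts
    per_plex = {}
    pooled_num = pd.Series(0.0, index=counts.index)
    pooled_den = pd.Series(0.0, index=counts.index)
    for plex in panel.plexes:
        c1 = [a.id for a in panel.amplicons_for_gene(g1, plex_id=plex)]
        c2 = [a.id for a in panel.amplicons_for_gene(g2, plex_id=plex)]
        s1 = counts[c1].sum(axis=1).astype(float)
        s2 = counts[c2].sum(axis=1).astype(float)
        for s, total in (("gene-1", s1), ("gene-2", s2)):
            zero = total[total == 0]
            if not zero.empty:
                raise ValueError(
                    f"zero {s} count sum in plex {plex!r} for sample "
                    f"{zero.index[0]!r}"
                )
        per_plex[plex] = s1 / s2
        pooled_num += s1
        pooled_den += s2
    per_plex_df = pd.DataFrame(per_plex)
    global_ratio = (
        pooled_num / pooled_den if pooled else per_plex_df.mean(axis=1)
    )
    cohort_mean = float(global_ratio.mean())
    cohort_sd = float(global_ratio.std(ddof=1)) if len(global_ratio) > 1 else 0.0

    flagged = {}
    for s in global_ratio.index:
        others = global_ratio.drop(index=s)
        if len(others) < 2:
            flagged[s] = False
            continue
        m, sd = float(others.mean()), float(others.std(ddof=1))
        flagged[s] = bool(abs(global_ratio[s] - m) > sd_multiplier * sd)
    return GeneRatioResult(
        per_plex=per_plex_df,
        global_ratio=global_ratio,
        cohort_mean=cohort_mean,
        cohort_sd=cohort_sd,
        flagged=pd.Series(flagged),
        sd_multiplier=sd_multiplier,
    )
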