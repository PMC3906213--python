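"""Probe-by-trait Pearson correlation with leave-pair-out sensitivity.

Correlations run on the beta scale (the scale on which methylation-vs-score
scatter is read), pooling individuals across the cohort.  Twin-pair
non-independence is acknowledged but not modelled here; p-values treat
samples as exchangeable, which is anticonservative for strongly pair-
clustered probes, and the output log says so.

The sensitivity analysis recomputes every correlation with chosen twin
pairs removed, reported side by side with the full-sample values, so
extreme-pair-driven associations can be separated from quantitative-
spectrum ones.  :func:`flag_extreme_pairs` operationalises "extreme pair"
as: both members above a score cutoff AND both beyond ``mad_k`` robust
(MAD) deviations from the cohort median at a minimum number of the listed
probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, TwinMethError, ValidationError

PAIR_NONINDEPENDENCE_NOTE = (
    "note: samples are twins; correlation p-values pool individuals and do "
    "not model within-pair dependence"
)


def _pearson_rows(matrix: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of a probes-by-samples matrix against one vector."""
    n = y.size
    xc = matrix - matrix.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return r, p


def probe_trait_correlation(
    beta: pd.DataFrame,
    traits: pd.DataFrame,
    trait: str = "total",
    min_n: int = 4,
) -> pd.DataFrame:
    """Pearson r and two-sided p per probe against one trait score.

    Probes with zero variance are skipped (correlation undefined there);
    a constant trait vector is an error.
    """
    scores = traits.set_index("sample_id")[trait]
    missing = [s for s in beta.columns if s not in scores.index]
    if missing:
        raise ValidationError(f"trait scores missing for sample(s) {missing[:5]}")
    y = scores.loc[beta.columns].to_numpy(float)
    if y.size < min_n:
        raise DesignError(f"need >= {min_n} scored samples, got {y.size}")
    if np.std(y) == 0:
        raise ValidationError(
            f"trait '{trait}' is constant across samples; correlation undefined"
        )
    mat = beta.to_numpy(float)
    variable = mat.std(axis=1) > 0
    r = np.full(mat.shape[0], np.nan)
    p = np.full(mat.shape[0], np.nan)
    r[variable], p[variable] = _pearson_rows(mat[variable], y)
    records = pd.DataFrame(
        {
            "probe_id": beta.index,
            "trait": trait,
            "n": y.size,
            "r": r,
            "p_value": p,
        }
    )
    return records.loc[variable].reset_index(drop=True)


def sensitivity_excluding_pairs(
    beta: pd.DataFrame,
    traits: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    trait: str,
    exclude_pairs: list[str],
    min_n: int = 4,
) -> pd.DataFrame:
    """Full-sample and pairs-excluded correlations side by side.

    An empty exclusion list reproduces :func:`probe_trait_correlation`
    exactly (the excluded columns just duplicate the full-sample ones).
    """
    known = set(sample_sheet["pair_id"])
    unknown = [p for p in exclude_pairs if p not in known]
    if unknown:
        raise DesignError(f"unknown pair id(s): {unknown}")
    drop = set(
        sample_sheet.loc[sample_sheet["pair_id"].isin(exclude_pairs), "sample_id"]
    )
    keep = [s for s in beta.columns if s not in drop]
    if len(keep) < min_n:
        raise DesignError("exclusion leaves too few samples for correlation")

    full = probe_trait_correlation(beta, traits, trait, min_n=min_n)
    reduced = probe_trait_correlation(beta[keep], traits, trait, min_n=min_n)
    reduced = reduced.rename(
        columns={"r": "r_excluded", "p_value": "p_value_excluded", "n": "n_excluded"}
    )[["probe_id", "n_excluded", "r_excluded", "p_value_excluded"]]
    out = full.merge(reduced, on="probe_id", how="left")
    out["excluded_pairs"] = ",".join(exclude_pairs)
    return out


def flag_extreme_pairs(
    beta: pd.DataFrame,
    traits: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    top_probes: list[str],
    score_cutoff: int = 25,
    trait: str = "total",
    mad_k: float = 3.0,
    min_probes: int = 5,
) -> list[str]:
    """Pairs that are joint outliers in phenotype and methylation.

    A pair is flagged when both members score above ``score_cutoff`` and
    both sit beyond ``mad_k`` MAD-based robust deviations from the cohort
    median at >= ``min_probes`` of the listed probes.
    """
    if not top_probes:
        raise TwinMethError("flag_extreme_pairs needs a non-empty probe list")
    scores = traits.set_index("sample_id")[trait]
    sub = beta.loc[[p for p in top_probes if p in beta.index]]
    med = sub.median(axis=1)
    mad = stats.median_abs_deviation(sub, axis=1, scale="normal")
    mad = np.where(mad == 0, np.inf, mad)
    outlying = sub.sub(med, axis=0).abs().div(mad, axis=0) > mad_k

    flagged = []
    for pair_id, members in sample_sheet.groupby("pair_id", sort=False):
        ids = members["sample_id"].tolist()
        if any(s not in scores.index or s not in beta.columns for s in ids):
            continue
        if not all(scores.loc[s] > score_cutoff for s in ids):
            continue
        joint = outlying[ids].all(axis=1).sum()
        if joint >= min_probes:
            flagged.append(pair_id)
    return flagged


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResults:
    """Per-probe correlation records for one trait, optionally with a
    pairs-excluded sensitivity column block."""

    records: pd.DataFrame
    trait: str
    n: int
    excluded_pairs: tuple[str, ...] = ()

    def top(self, k: int = 10) -> pd.DataFrame:
        return (
            self.records.reindex(
                self.records["r"].abs().sort_values(ascending=False).index
            )
            .head(k)
            .reset_index(drop=True)
        )

    def summary(self, k: int = 10) -> str:
        lines = [
            f"Probe-trait correlation - trait '{self.trait}', n={self.n}",
            PAIR_NONINDEPENDENCE_NOTE,
        ]
        if self.excluded_pairs:
            lines.append(f"sensitivity: excluding pair(s) {list(self.excluded_pairs)}")
        lines.append("")
        cols = [c for c in ("probe_id", "n", "r", "p_value", "n_excluded",
                            "r_excluded", "p_value_excluded")
                if c in self.records.columns]
        lines.append(
            self.top(k)[cols].to_string(index=False,
                                        float_format=lambda v: f"{v:.4g}")
        )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6g")


class TraitCorrelation:
    """Correlation model between methylation and one quantitative trait.

    ``fit()`` computes per-probe Pearson correlations; passing
    ``exclude_pairs`` adds the leave-pairs-out sensitivity block.
    """

    def __init__(self, beta, traits, sample_sheet=None, trait: str = "total"):
        self.beta = beta
        self.traits = traits
        self.sample_sheet = sample_sheet
        self.trait = trait

    def fit(self, exclude_pairs: list[str] | None = None) -> CorrelationResults:
        if exclude_pairs:
            if self.sample_sheet is None:
                raise ValidationError("pair exclusion requires a sample sheet")
            records = sensitivity_excluding_pairs(
                self.beta, self.traits, self.sample_sheet, self.trait, exclude_pairs
            )
        else:
            records = probe_trait_correlation(self.beta, self.traits, self.trait)
        return CorrelationResults(
            records=records,
            trait=self.trait,
            n=len(self.beta.columns),
            excluded_pairs=tuple(exclude_pairs or ()),
        )
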