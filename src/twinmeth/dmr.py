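"""Differential methylation analyses for the twin designs.

Four complementary strategies:

* **Within-pair** (:class:`WithinPairDMA`): one-sample t-test of
  transformed affected-minus-unaffected differences against zero
  (equivalent to a paired t-test), per probe, across the discordant pairs
  of a design.
* **Between-group** (:class:`BetweenGroupDMA`): Welch two-sample t-test on
  transformed values, e.g. ASD cases vs unrelated controls or sporadic vs
  familial cases, restricted to autosomes by default.
* **Family-private screen** (:func:`family_screen`): per pair, every probe
  with |delta-beta| at or above a large-effect threshold (default 0.15),
  annotated with other pairs hitting the same probe in the same direction.
* **Distribution skew** (:func:`skew_test`): two-sample Kolmogorov-Smirnov
  comparison of per-probe average |delta-beta| between discordant and
  unaffected-concordant pairs, plus the top-k mean |delta-beta| contrast.

Ranking combines statistical significance and effect magnitude: probes are
ranked by p ascending and by |mean delta-beta| descending, and ordered by
the rank sum, so a locus must do well on both axes to head the list.
Significance is always computed on the variance-stabilized scale; reported
effect sizes are plain beta differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, TwinMethError, ValidationError

#: Designs selecting discordant pairs; 'combined' pools every discordant pair.
PAIR_DESIGNS = ("asd", "social", "rrbi", "communication", "combined", "unaffected")

_DESIGN_GROUPS = {
    "asd": ("discordant_asd",),
    "social": ("discordant_social",),
    "rrbi": ("discordant_rrbi",),
    "communication": ("discordant_communication",),
    "combined": (
        "discordant_asd",
        "discordant_social",
        "discordant_rrbi",
        "discordant_communication",
    ),
    "unaffected": ("concordant_unaffected",),
}

_FOCAL_FLAG = {
    "discordant_asd": "asd_affected",
    "discordant_social": "social_affected",
    "discordant_rrbi": "rrbi_affected",
    "discordant_communication": "communication_affected",
}


# ---------------------------------------------------------------------------
# Pair deltas
# ---------------------------------------------------------------------------


@dataclass
class PairDelta:
    """Probe-by-pair difference matrices on both scales.

    Columns are pair ids; orientation is affected minus unaffected for
    discordant designs.  Concordant-unaffected pairs have no affected
    member; their orientation is member A minus member B, which is
    irrelevant for the magnitude-based uses they serve.
    """

    beta: pd.DataFrame
    transformed: pd.DataFrame
    design: str

    @property
    def pairs(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_pairs(self) -> int:
        return self.beta.shape[1]


def pair_deltas(
    beta: pd.DataFrame,
    transformed: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    design: str,
) -> PairDelta:
    """Affected-minus-unaffected differences for every pair of a design."""
    if design not in PAIR_DESIGNS:
        raise DesignError(f"unknown design '{design}'; allowed: {PAIR_DESIGNS}")
    groups = _DESIGN_GROUPS[design]
    sel = sample_sheet[sample_sheet["group"].isin(groups)]
    if sel.empty:
        raise DesignError(f"design '{design}' selects no pairs from this sheet")

    beta_cols, trans_cols, pair_ids = [], [], []
    for pair_id, members in sel.groupby("pair_id", sort=False):
        group = members["group"].iloc[0]
        focal = _FOCAL_FLAG.get(group)
        if focal is None:
            ordered = members.sort_values("member")
            a, b = ordered["sample_id"].tolist()
        else:
            affected = members[members[focal]]
            if len(affected) != 1:
                raise DesignError(
                    f"pair {pair_id!r} lacks a unique affected member for "
                    f"design '{design}' ({len(affected)} affected)"
                )
            a = affected["sample_id"].iloc[0]
            b = members.loc[members["sample_id"] != a, "sample_id"].iloc[0]
        beta_cols.append(beta[a] - beta[b])
        trans_cols.append(transformed[a] - transformed[b])
        pair_ids.append(pair_id)

    return PairDelta(
        beta=pd.concat(beta_cols, axis=1, keys=pair_ids),
        transformed=pd.concat(trans_cols, axis=1, keys=pair_ids),
        design=design,
    )


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def within_pair_test(delta: PairDelta) -> tuple[pd.DataFrame, list[str]]:
    """Per-probe one-sample t-test of transformed deltas against zero.

    Returns (records, degenerate_probe_ids); zero-variance probes cannot
    support a t-test and are excluded from ranking.
    """
    if delta.n_pairs < 2:
        raise DesignError(
            "within-pair testing needs >=2 discordant pairs; for a single "
            "pair use family_screen instead"
        )
    tr = delta.transformed.to_numpy()
    sd = tr.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_1samp(tr, popmean=0.0, axis=1)
    records = pd.DataFrame(
        {
            "probe_id": delta.beta.index,
            "mean_delta_beta": delta.beta.to_numpy().mean(axis=1),
            "t": res.statistic,
            "p_value": res.pvalue,
        }
    )
    degenerate_ids = records.loc[degenerate, "probe_id"].tolist()
    return records.loc[~degenerate].reset_index(drop=True), degenerate_ids


def between_group_test(
    transformed: pd.DataFrame,
    beta: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-probe Welch t-test, cases vs controls, on transformed values.

    Effect size is mean beta(cases) minus mean beta(controls).
    """
    overlap = set(case_ids) & set(control_ids)
    if overlap:
        raise DesignError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise DesignError("both groups need >=2 samples for a Welch t-test")
    x = transformed[list(case_ids)].to_numpy()
    y = transformed[list(control_ids)].to_numpy()
    degenerate = (x.std(axis=1, ddof=1) == 0) & (y.std(axis=1, ddof=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    records = pd.DataFrame(
        {
            "probe_id": transformed.index,
            "mean_delta_beta": beta[list(case_ids)].to_numpy().mean(axis=1)
            - beta[list(control_ids)].to_numpy().mean(axis=1),
            "t": res.statistic,
            "p_value": res.pvalue,
        }
    )
    degenerate_ids = records.loc[degenerate, "probe_id"].tolist()
    records = records.loc[~degenerate]
    # identical groups give 0/0 -> nan; by continuity no evidence at all
    records.loc[records["p_value"].isna(), ["t", "p_value"]] = [0.0, 1.0]
    return records.reset_index(drop=True), degenerate_ids


# ---------------------------------------------------------------------------
# Combined ranking
# ---------------------------------------------------------------------------


def combined_rank(
    records: pd.DataFrame, method: str = "rank_sum", alpha: float = 0.05
) -> pd.DataFrame:
    """Order probes by significance and magnitude together.

    ``p_rank`` ranks p ascending, ``magnitude_rank`` ranks |mean
    delta-beta| descending (average ranks on ties); the combined score is
    their sum (or product for ``method='rank_product'``).  The final order
    is ascending combined score, ties broken by smaller p, then probe id,
    producing a unique positive-integer ``rank``.  A Bonferroni flag marks
    p below alpha divided by the number of probes tested; it annotates,
    never truncates.
    """
    if method not in ("rank_sum", "rank_product"):
        raise TwinMethError(f"unknown ranking method '{method}'")
    out = records.copy()
    if out.empty:
        for col in ("p_rank", "magnitude_rank", "combined_score", "rank"):
            out[col] = pd.Series(dtype=float)
        out["bonferroni_significant"] = pd.Series(dtype=bool)
        return out
    out["p_rank"] = out["p_value"].rank(method="average", ascending=True)
    out["magnitude_rank"] = (
        out["mean_delta_beta"].abs().rank(method="average", ascending=False)
    )
    if method == "rank_sum":
        out["combined_score"] = out["p_rank"] + out["magnitude_rank"]
    else:
        out["combined_score"] = out["p_rank"] * out["magnitude_rank"]
    out["bonferroni_significant"] = out["p_value"] < alpha / len(out)
    out = out.sort_values(
        ["combined_score", "p_value", "probe_id"], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def annotate(records: pd.DataFrame, manifest: pd.DataFrame | None) -> pd.DataFrame:
    if manifest is None:
        out = records.copy()
        for col in ("gene", "chromosome", "position"):
            if col not in out.columns:
                out[col] = ""
        return out
    anno = manifest.set_index("probe_id")[["gene", "chromosome", "position"]]
    return records.join(anno, on="probe_id")


# ---------------------------------------------------------------------------
# Results object
# ---------------------------------------------------------------------------


@dataclass
class DmrResults:
    """Ranked differential methylation results for one analysis design."""

    records: pd.DataFrame
    design: str
    n_units: int  # pairs (within-pair) or min group size (between-group)
    n_probes_tested: int
    bonferroni_cutoff: float
    degenerate_probes: list[str] = field(default_factory=list)
    rank_method: str = "rank_sum"

    def top(self, k: int = 50) -> pd.DataFrame:
        return self.records.head(k)

    def summary(self, k: int = 10) -> str:
        head = self.top(k)
        lines = [
            f"Differential methylation - design '{self.design}'",
            f"probes tested: {self.n_probes_tested}  "
            f"(degenerate excluded: {len(self.degenerate_probes)})",
            f"ranking: {self.rank_method} of p-rank and |delta-beta|-rank",
            f"Bonferroni cutoff (0.05 / {self.n_probes_tested}): "
            f"{self.bonferroni_cutoff:.3g}; significant probes: "
            f"{int(self.records['bonferroni_significant'].sum())}",
            "",
        ]
        cols = ["rank", "probe_id", "gene", "chromosome", "position",
                "mean_delta_beta", "p_value"]
        cols = [c for c in cols if c in head.columns]
        lines.append(head[cols].to_string(index=False,
                                          float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from .arrayio import write_dmr_table

        write_dmr_table(self.records, path)


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------


class WithinPairDMA:
    """Within-pair differential methylation model for one discordant design.

    Parameters
    ----------
    beta, transformed : DataFrame
        Probe-by-sample methylation on the beta and variance-stabilized
        scales (same probes, same samples).
    sample_sheet : DataFrame
        Twin pairing and phenotype flags.
    design : str
        'asd', 'social', 'rrbi', 'communication' or 'combined'.
    manifest : DataFrame, optional
        Probe annotation for gene/position columns in the output.
    """

    def __init__(self, beta, transformed, sample_sheet, design, manifest=None):
        self.beta = beta
        self.transformed = transformed
        self.sample_sheet = sample_sheet
        self.design = design
        self.manifest = manifest
        self.delta = pair_deltas(beta, transformed, sample_sheet, design)

    def fit(self, rank_method: str = "rank_sum", alpha: float = 0.05) -> DmrResults:
        records, degenerate = within_pair_test(self.delta)
        records = combined_rank(records, method=rank_method, alpha=alpha)
        records = annotate(records, self.manifest)
        records["design"] = self.design
        return DmrResults(
            records=records,
            design=self.design,
            n_units=self.delta.n_pairs,
            n_probes_tested=len(records),
            bonferroni_cutoff=alpha / max(len(records), 1),
            degenerate_probes=degenerate,
            rank_method=rank_method,
        )


class BetweenGroupDMA:
    """Between-group (case vs control) differential methylation model.

    Welch t-test on transformed values; autosome restriction is applied by
    default (requires a manifest) because mixed-sex groups would otherwise
    show sex-chromosome differences unrelated to phenotype.
    """

    def __init__(
        self,
        beta,
        transformed,
        case_ids,
        control_ids,
        manifest=None,
        design: str = "case_control",
        autosomes_only: bool = True,
    ):
        self.beta = beta
        self.transformed = transformed
        self.case_ids = list(case_ids)
        self.control_ids = list(control_ids)
        self.manifest = manifest
        self.design = design
        self.autosomes_only = autosomes_only
        self.n_removed_sex = 0

    def fit(self, rank_method: str = "rank_sum", alpha: float = 0.05) -> DmrResults:
        beta, transformed = self.beta, self.transformed
        if self.autosomes_only:
            if self.manifest is None:
                raise ValidationError("autosome restriction requires a manifest")
            from .preprocess import restrict_autosomes

            keep, removed = restrict_autosomes(transformed.index, self.manifest)
            self.n_removed_sex = removed
            beta, transformed = beta.loc[keep], transformed.loc[keep]
        records, degenerate = between_group_test(
            transformed, beta, self.case_ids, self.control_ids
        )
        records = combined_rank(records, method=rank_method, alpha=alpha)
        records = annotate(records, self.manifest)
        records["design"] = self.design
        return DmrResults(
            records=records,
            design=self.design,
            n_units=min(len(self.case_ids), len(self.control_ids)),
            n_probes_tested=len(records),
            bonferroni_cutoff=alpha / max(len(records), 1),
            degenerate_probes=degenerate,
            rank_method=rank_method,
        )


# ---------------------------------------------------------------------------
# Family-private screen
# ---------------------------------------------------------------------------


def family_screen(delta: PairDelta, threshold: float = 0.15) -> pd.DataFrame:
    """Large within-pair effects, per pair, with shared-direction annotation.

    A hit is |delta-beta| >= threshold (inclusive).  ``shared_with`` lists
    the other pairs exceeding the threshold at the same probe with the
    same sign, separated by commas.
    """
    if not 0.0 < threshold < 1.0:
        raise TwinMethError(f"family-screen threshold {threshold} outside (0, 1)")
    d = delta.beta
    mask = d.abs() >= threshold
    rows = []
    hit_probes = d.index[mask.any(axis=1)]
    for probe in hit_probes:
        hits = [(pair, d.at[probe, pair]) for pair in d.columns
                if mask.at[probe, pair]]
        for pair, value in hits:
            shared = [q for q, v in hits if q != pair and np.sign(v) == np.sign(value)]
            rows.append(
                {
                    "probe_id": probe,
                    "pair_id": pair,
                    "delta_beta": value,
                    "direction": "hyper" if value > 0 else "hypo",
                    "shared_with": ",".join(shared),
                }
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "pair_id", "delta_beta", "direction", "shared_with"]
    )


# ---------------------------------------------------------------------------
# Distribution skew
# ---------------------------------------------------------------------------


@dataclass
class SkewResult:
    ks_statistic: float
    p_value: float
    top_mean_abs_discordant: float | None = None
    top_mean_abs_comparison: float | None = None
    top_k: int | None = None


def skew_test(
    delta_discordant: PairDelta,
    delta_comparison: PairDelta,
    ranked: pd.DataFrame | None = None,
    top_k: int = 50,
) -> SkewResult:
    """KS comparison of per-probe average |delta-beta| distributions.

    An excess of probes with large average within-pair differences in the
    discordant group shifts its distribution right.  When a ranked record
    table for the discordant design is supplied, the mean within-pair
    |delta-beta| over its top-k probes is also reported for each group
    (the top-hit specificity contrast).
    """
    x = delta_discordant.beta.abs().mean(axis=1)
    y = delta_comparison.beta.abs().mean(axis=1)
    if x.equals(y) or np.array_equal(x.to_numpy(), y.to_numpy()):
        res_stat, res_p = 0.0, 1.0
    else:
        res = stats.ks_2samp(x.to_numpy(), y.to_numpy(), method="asymp")
        res_stat, res_p = float(res.statistic), float(res.pvalue)
    out = SkewResult(ks_statistic=res_stat, p_value=res_p)
    if ranked is not None:
        top = ranked.head(top_k)["probe_id"]
        out.top_mean_abs_discordant = float(x.loc[top].mean())
        out.top_mean_abs_comparison = float(y.loc[top].mean())
        out.top_k = top_k
    return out


# ---------------------------------------------------------------------------
# Cross-design overlap
# ---------------------------------------------------------------------------


def cross_design_overlap(
    results: dict[str, DmrResults], k: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k probes of every design with their ranks everywhere else,
    plus the Spearman correlation of full combined-score vectors.

    Returns (overlap table, design-by-design correlation matrix).
    """
    if len(results) < 2:
        raise DesignError("cross-design overlap needs >=2 ranked lists")
    designs = list(results)
    rank_maps = {
        d: res.records.set_index("probe_id")["rank"] for d, res in results.items()
    }
    top_probes: list[str] = []
    for d in designs:
        for probe in results[d].top(k)["probe_id"]:
            if probe not in top_probes:
                top_probes.append(probe)
    overlap = pd.DataFrame({"probe_id": top_probes})
    for d in designs:
        overlap[f"rank_{d}"] = [rank_maps[d].get(p, np.nan) for p in top_probes]
    overlap["n_designs_top_k"] = (
        overlap[[f"rank_{d}" for d in designs]].le(k).sum(axis=1)
    )

    score_maps = {
        d: res.records.set_index("probe_id")["combined_score"]
        for d, res in results.items()
    }
    corr = pd.DataFrame(np.eye(len(designs)), index=designs, columns=designs)
    for i, a in enumerate(designs):
        for b in designs[i + 1 :]:
            common = score_maps[a].index.intersection(score_maps[b].index)
            rho = stats.spearmanr(
                score_maps[a].loc[common], score_maps[b].loc[common]
            ).statistic
            corr.loc[a, b] = corr.loc[b, a] = rho
    return overlap, corr
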