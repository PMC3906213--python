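"""Probe QC, quantile normalization, beta computation, and the empirical
variance-stabilizing transform.

Processing order in :func:`preprocess` follows the array pipeline the
package implements: probes failing detection (p > 0.05 in any sample) and
blacklisted probes are dropped first; the methylated and unmethylated
signal layers are then quantile-normalized separately across samples;
beta = M / (M + U); finally a monotone probit transform of the pooled
empirical beta distribution flattens the bimodal shape so downstream
t-statistics see approximately homoskedastic values.  Statistical tests run
on the transformed scale while effect sizes (delta-beta) are always
reported on the beta scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .arrayio import SEX_CHROMOSOMES, SignalSet
from .exceptions import ValidationError


# ---------------------------------------------------------------------------
# Filter report
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Probe accounting across QC stages.

    Each probe is counted once, under the first rule that removed it
    (detection before blacklist before undefined-beta); the counts always
    reconcile: n_input = n_retained + all removals.
    """

    n_input: int
    n_removed_detection: int = 0
    n_removed_blacklist: int = 0
    n_removed_undefined: int = 0
    n_removed_sex_chromosomes: int = 0
    n_retained: int = 0
    removed: dict[str, list[str]] = field(default_factory=dict)

    def check(self) -> None:
        total = (
            self.n_retained
            + self.n_removed_detection
            + self.n_removed_blacklist
            + self.n_removed_undefined
            + self.n_removed_sex_chromosomes
        )
        if total != self.n_input:
            raise ValidationError(
                f"filter report does not reconcile: input {self.n_input} != "
                f"retained {self.n_retained} + removals {total - self.n_retained}"
            )

    def log_lines(self) -> list[str]:
        return [
            f"probes in: {self.n_input}",
            f"removed, detection p > threshold in >=1 sample: "
            f"{self.n_removed_detection}",
            f"removed, blacklisted: {self.n_removed_blacklist}",
            f"removed, undefined beta (M+U=0): {self.n_removed_undefined}",
            f"removed, sex chromosomes: {self.n_removed_sex_chromosomes}",
            f"probes retained: {self.n_retained}",
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"probe_id": pid, "reason": reason}
            for reason, ids in self.removed.items()
            for pid in ids
        ]
        return pd.DataFrame(rows, columns=["probe_id", "reason"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------


def filter_probes(
    signals: SignalSet,
    manifest: pd.DataFrame,
    detection_threshold: float = 0.05,
) -> tuple[SignalSet, FilterReport]:
    """Drop probes failing detection in any sample, then blacklisted probes.

    The detection rule is strictly greater-than: a probe with p exactly at
    the threshold in every sample is kept.
    """
    report = FilterReport(n_input=len(signals.probes))
    fails_detection = (signals.detection_p > detection_threshold).any(axis=1)
    detection_ids = signals.probes[fails_detection]

    blacklisted = set(manifest.loc[manifest["blacklisted"], "probe_id"])
    remaining = signals.probes[~fails_detection]
    blacklist_ids = remaining[remaining.isin(blacklisted)]
    retained = remaining[~remaining.isin(blacklisted)]

    report.n_removed_detection = len(detection_ids)
    report.n_removed_blacklist = len(blacklist_ids)
    report.n_retained = len(retained)
    report.removed["detection"] = list(detection_ids)
    report.removed["blacklist"] = list(blacklist_ids)
    report.check()
    if report.n_retained == 0:
        raise ValidationError("all probes removed by QC; nothing to analyse")
    return signals.loc_probes(retained), report


def restrict_autosomes(
    probe_ids: pd.Index | list[str], manifest: pd.DataFrame
) -> tuple[pd.Index, int]:
    """Drop X and Y probes; returns (retained ids, number removed).

    Used by between-group designs, where mixed-sex groups would otherwise
    pick up sex-linked methylation differences.
    """
    probe_ids = pd.Index(probe_ids)
    anno = manifest.set_index("probe_id")["chromosome"]
    missing = probe_ids[~probe_ids.isin(anno.index)]
    if len(missing):
        raise ValidationError(
            f"probe(s) missing from manifest: {missing.tolist()[:5]}"
        )
    chrom = anno.loc[probe_ids]
    keep = probe_ids[~chrom.isin(SEX_CHROMOSOMES).to_numpy()]
    return keep, len(probe_ids) - len(keep)


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------


def quantile_normalize(layer: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean-of-sorted-columns reference.

    Ties within a column receive the mean of the reference values their
    rank positions span.  Idempotent; a single-column input is returned
    unchanged with a warning (there is nothing to normalize against).
    """
    if layer.shape[1] < 2:
        warnings.warn(
            "quantile normalization needs >=2 samples; returning input unchanged",
            stacklevel=2,
        )
        return layer.copy()
    if layer.isna().any().any():
        raise ValidationError("quantile normalization does not accept missing values")
    arr = layer.to_numpy(float)
    n, _ = arr.shape
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie runs over the sorted column; each run gets the mean of the
        # reference values it spans
        starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        counts = np.diff(np.r_[starts, n])
        run_means = np.add.reduceat(ref, starts) / counts
        out[order, j] = np.repeat(run_means, counts)
    return pd.DataFrame(out, index=layer.index, columns=layer.columns)


# ---------------------------------------------------------------------------
# Beta computation
# ---------------------------------------------------------------------------


def compute_beta(
    methylated: pd.DataFrame, unmethylated: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """beta = M / (M + U), no offset constant.

    Returns (beta, undefined): entries with M + U = 0 have no defined
    methylation fraction; they are NaN in beta and True in the undefined
    mask, and the caller routes affected probes to the filter report.
    """
    m = np.asarray(methylated, float)
    u = np.asarray(unmethylated, float)
    if (m < 0).any() or (u < 0).any():
        raise ValidationError("negative signal intensities; beta is undefined")
    total = m + u
    undefined = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(undefined, np.nan, m / np.where(undefined, 1.0, total))
    if isinstance(methylated, pd.DataFrame):
        idx, cols = methylated.index, methylated.columns
        return (
            pd.DataFrame(b, index=idx, columns=cols),
            pd.DataFrame(undefined, index=idx, columns=cols),
        )
    return pd.DataFrame(b), pd.DataFrame(undefined)


# ---------------------------------------------------------------------------
# Empirical variance-stabilizing transform
# ---------------------------------------------------------------------------


class EmpiricalNormalVST:
    """Probit transform of the pooled empirical beta distribution.

    Fitting stores the pooled empirical CDF (midrank convention, so the
    pooled median maps exactly to zero); ``transform`` sends beta to the
    standard-normal quantile of its CDF value, interpolating linearly
    between observed values.  The map is strictly monotone and invertible
    on the reference range, and flattens the bimodal beta distribution so
    per-probe sampling variance is roughly constant across the scale.
    """

    def __init__(self) -> None:
        self.values_: np.ndarray | None = None
        self.cdf_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.values_ is not None

    def fit(self, beta: pd.DataFrame | np.ndarray) -> "EmpiricalNormalVST":
        pooled = np.asarray(beta, float).ravel()
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size == 0:
            raise ValidationError("cannot fit VST on empty input")
        values, counts = np.unique(pooled, return_counts=True)
        if values.size < 2:
            raise ValidationError(
                "degenerate (constant) beta input; empirical CDF is not invertible"
            )
        n = pooled.size
        below = np.concatenate(([0], np.cumsum(counts)[:-1]))
        self.values_ = values
        self.cdf_ = (below + 0.5 * counts) / n  # midrank ECDF, strictly in (0,1)
        return self

    def _require_fit(self) -> None:
        if not self.fitted:
            raise ValidationError("VST has not been fitted")

    def ecdf(self, x) -> np.ndarray:
        self._require_fit()
        return np.interp(np.asarray(x, float), self.values_, self.cdf_)

    def transform(self, beta: pd.DataFrame | np.ndarray):
        self._require_fit()
        arr = np.asarray(beta, float)
        p = np.clip(np.interp(arr, self.values_, self.cdf_), 1e-15, 1 - 1e-15)
        z = stats.norm.ppf(p)
        if isinstance(beta, pd.DataFrame):
            return pd.DataFrame(z, index=beta.index, columns=beta.columns)
        return z

    def fit_transform(self, beta: pd.DataFrame):
        return self.fit(beta).transform(beta)

    def inverse(self, z):
        """Inverse on the reference range (values outside it are clamped)."""
        self._require_fit()
        p = stats.norm.cdf(np.asarray(z, float))
        return np.interp(p, self.cdf_, self.values_)

    def reference_frame(self, n_points: int = 10001) -> pd.DataFrame:
        """Quantile-grid snapshot of the fitted reference, for serialization.

        The snapshot reproduces the transform by interpolation to roughly
        grid resolution; the in-memory object is exact.
        """
        self._require_fit()
        if self.values_.size <= n_points:
            vals, cdf = self.values_, self.cdf_
        else:
            idx = np.unique(
                np.round(np.linspace(0, self.values_.size - 1, n_points)).astype(int)
            )
            vals, cdf = self.values_[idx], self.cdf_[idx]
        return pd.DataFrame({"beta": vals, "ecdf": cdf})

    @classmethod
    def from_reference_frame(cls, frame: pd.DataFrame) -> "EmpiricalNormalVST":
        obj = cls()
        obj.values_ = frame["beta"].to_numpy(float)
        obj.cdf_ = frame["ecdf"].to_numpy(float)
        return obj


class EmpiricalVarianceVST:
    """Variance-stabilizing transform from the empirical noise profile.

    Stabilizes the *sampling* variance of beta across its range: per-probe
    across-sample standard deviations are pooled into quantile bins of the
    probe mean, giving a robust (bin-median) estimate ``s(beta)`` of the
    measurement spread at each methylation level; the transform is

        T(beta) = integral_0^beta  du / s(u)

    (piecewise-linear ``s``, trapezoid integration on a fine grid), centred
    so the pooled median maps to zero.  Where the array compresses values
    against 0 and 1 the local spread shrinks, so ``1/s`` stretches the
    extremes of the bimodal scale; where the spread is flat the transform
    is essentially affine and per-probe t-statistics are unchanged.
    Strictly monotone, invertible on [0, 1], and reproducible from its
    stored (grid, T) reference.
    """

    def __init__(self, n_bins: int = 50, grid_points: int = 2001,
                 floor_frac: float = 0.05) -> None:
        self.n_bins = n_bins
        self.grid_points = grid_points
        self.floor_frac = floor_frac
        self.grid_: np.ndarray | None = None
        self.t_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.grid_ is not None

    def fit(self, beta: pd.DataFrame | np.ndarray) -> "EmpiricalVarianceVST":
        arr = np.asarray(beta, float)
        arr = arr[~np.isnan(arr).any(axis=1)] if arr.ndim == 2 else arr[None, :]
        if arr.size == 0 or arr.shape[1] < 2:
            raise ValidationError("variance VST needs >=2 samples per probe")
        means = arr.mean(axis=1)
        sds = arr.std(axis=1, ddof=1)
        if np.unique(arr).size < 2:
            raise ValidationError(
                "degenerate (constant) beta input; no variance profile to fit"
            )
        # robust binned spread profile over the observed beta range
        order = np.argsort(means, kind="stable")
        n_bins = min(self.n_bins, max(1, arr.shape[0] // 20))
        splits = np.array_split(order, n_bins)
        centers, spread = [], []
        for chunk in splits:
            if chunk.size == 0:
                continue
            centers.append(float(np.median(means[chunk])))
            spread.append(float(np.median(sds[chunk])))
        centers, spread = np.asarray(centers), np.asarray(spread)
        positive = spread[spread > 0]
        if positive.size == 0:
            # no measured spread anywhere: transform degenerates to identity
            centers, spread = np.array([0.0, 1.0]), np.array([1.0, 1.0])
        else:
            floor = self.floor_frac * float(np.median(positive))
            spread = np.maximum(spread, floor)

        grid = np.linspace(0.0, 1.0, self.grid_points)
        s_on_grid = np.interp(grid, centers, spread)
        inv = 1.0 / s_on_grid
        t = np.concatenate(
            ([0.0], np.cumsum((inv[1:] + inv[:-1]) / 2.0 * np.diff(grid)))
        )
        pooled_median = float(np.median(arr))
        t -= np.interp(pooled_median, grid, t)
        self.grid_, self.t_ = grid, t
        return self

    def _require_fit(self) -> None:
        if not self.fitted:
            raise ValidationError("VST has not been fitted")

    def transform(self, beta: pd.DataFrame | np.ndarray):
        self._require_fit()
        arr = np.asarray(beta, float)
        z = np.interp(arr, self.grid_, self.t_)
        if isinstance(beta, pd.DataFrame):
            return pd.DataFrame(z, index=beta.index, columns=beta.columns)
        return z

    def fit_transform(self, beta: pd.DataFrame):
        return self.fit(beta).transform(beta)

    def inverse(self, z):
        self._require_fit()
        return np.interp(np.asarray(z, float), self.t_, self.grid_)

    def reference_frame(self, n_points: int = 10001) -> pd.DataFrame:
        self._require_fit()
        return pd.DataFrame({"beta": self.grid_, "transformed": self.t_})

    @classmethod
    def from_reference_frame(cls, frame: pd.DataFrame) -> "EmpiricalVarianceVST":
        obj = cls()
        obj.grid_ = frame["beta"].to_numpy(float)
        obj.t_ = frame["transformed"].to_numpy(float)
        return obj


#: Selectable transform strategies for :func:`preprocess`.
VST_STRATEGIES = {
    "variance": EmpiricalVarianceVST,
    "probit": EmpiricalNormalVST,
}


# ---------------------------------------------------------------------------
# End-to-end preprocessing
# ---------------------------------------------------------------------------


@dataclass
class PreprocessResult:
    beta: pd.DataFrame
    transformed: pd.DataFrame
    vst: "EmpiricalVarianceVST | EmpiricalNormalVST"
    report: FilterReport


def preprocess(
    signals: SignalSet,
    manifest: pd.DataFrame,
    detection_threshold: float = 0.05,
    vst: str = "variance",
) -> PreprocessResult:
    """Filter -> quantile-normalize each signal layer -> beta -> VST.

    ``vst`` selects the transform strategy: ``'variance'`` (empirical
    sampling-variance stabilization, the default) or ``'probit'``
    (probit of the pooled empirical CDF, which flattens the marginal).
    """
    filtered, report = filter_probes(signals, manifest, detection_threshold)
    meth = quantile_normalize(filtered.methylated)
    unmeth = quantile_normalize(filtered.unmethylated)
    beta, undefined = compute_beta(meth, unmeth)
    bad = undefined.any(axis=1)
    if bad.any():
        dropped = beta.index[bad]
        report.n_removed_undefined = len(dropped)
        report.n_retained -= len(dropped)
        report.removed["undefined_beta"] = list(dropped)
        beta = beta.loc[~bad]
        report.check()
    if vst not in VST_STRATEGIES:
        raise ValidationError(
            f"unknown VST strategy '{vst}'; allowed: {sorted(VST_STRATEGIES)}"
        )
    fitted = VST_STRATEGIES[vst]().fit(beta)
    transformed = fitted.transform(beta)
    return PreprocessResult(beta=beta, transformed=transformed, vst=fitted,
                            report=report)
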