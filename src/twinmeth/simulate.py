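"""Ground-truthed cohort simulator.

Generates everything the downstream analyses consume: probe-level
two-channel intensities with detection p-values, a probe manifest, a twin
sample sheet, quantitative trait scores, and a truth table recording every
planted effect.

Generative model
----------------
Beta values come first; intensities are back-derived.  For probe *g* the
population mean ``m_g`` is drawn from a two-component Gaussian mixture on
the beta scale (bimodal, as on promoter-focused arrays).  Twin pair *k*
shares a baseline ``m_g + b_gk`` (pair deviation, sd ``between_pair_sd``);
each member adds independent noise (sd ``within_pair_noise_sd``).  Planted
effects are additive on the beta scale, then everything is clipped to
[0, 1].  Total signal per probe-by-sample is log-normal and split as
``(beta * S, (1 - beta) * S)``, so methylated / (methylated + unmethylated)
recovers the intended beta up to float rounding.

All randomness flows from the single config seed through named
sub-streams, so each table is reproducible independently of the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arrayio import SignalSet
from .config import (
    AT_RISK_CUTOFF,
    SUBSCALE_ITEMS,
    SimulationConfig,
)
from .exceptions import ConfigError

_GROUP_ORDER = (
    "discordant_asd",
    "concordant_asd",
    "discordant_social",
    "discordant_rrbi",
    "discordant_communication",
    "concordant_unaffected",
)

# latent trait means: affected domains sit high, unaffected low, so ASD
# twins land above the at-risk cutoff and unaffected twins near the floor
_LATENT_AFFECTED = 0.8
_LATENT_UNAFFECTED = -1.1
_LATENT_PAIR_SD = 0.6
_LATENT_IND_SD = 0.4

# trait-locus betas are centred mid-range so the [0,1] clip cannot bite
_TRAIT_LOCUS_MEAN = 0.5
_TRAIT_LOCUS_SD = 0.08

_MEAN_LOG_TOTAL_SIGNAL = np.log(2000.0)
_SD_LOG_TOTAL_SIGNAL = 0.35


@dataclass
class Cohort:
    """Everything one simulated study produces."""

    signals: SignalSet
    manifest: pd.DataFrame
    sample_sheet: pd.DataFrame
    traits: pd.DataFrame
    truth: pd.DataFrame
    #: noiseless-channel beta values actually planted (probes x samples)
    beta_true: pd.DataFrame


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named child generators derived deterministically from one seed."""
    names = ("sheet", "manifest", "beta", "traits", "trait_loci",
             "signal", "artifacts")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


def make_sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    pair_no = 0
    for group in _GROUP_ORDER:
        for _ in range(config.group_pair_counts[group]):
            pair_no += 1
            pair_id = f"P{pair_no:02d}"
            sex = rng.choice(["M", "F"])
            affected_member = rng.choice(["A", "B"])
            for member in ("A", "B"):
                flags = dict.fromkeys(
                    ("asd_affected", "social_affected", "rrbi_affected",
                     "communication_affected"),
                    False,
                )
                familial = ""
                if group == "concordant_asd":
                    flags = dict.fromkeys(flags, True)
                    familial = "familial"
                elif group == "discordant_asd" and member == affected_member:
                    flags = dict.fromkeys(flags, True)
                    familial = "sporadic"
                elif group == "discordant_social" and member == affected_member:
                    flags["social_affected"] = True
                elif group == "discordant_rrbi" and member == affected_member:
                    flags["rrbi_affected"] = True
                elif group == "discordant_communication" and member == affected_member:
                    flags["communication_affected"] = True
                rows.append(
                    {
                        "sample_id": f"{pair_id}-{member}",
                        "pair_id": pair_id,
                        "member": member,
                        "sex": sex,
                        "group": group,
                        **flags,
                        "familial_class": familial,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------


def make_manifest(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    n_y = int(round(config.y_probe_frac * n))
    n_x = int(round(config.x_probe_frac * n))
    chroms = np.array(["0"] * n, dtype=object)
    order = rng.permutation(n)
    chroms[order[:n_x]] = "X"
    chroms[order[n_x : n_x + n_y]] = "Y"
    autosomal = order[n_x + n_y :]
    chroms[autosomal] = rng.integers(1, 23, size=autosomal.size).astype(str)
    positions = rng.integers(1, 200_000_000, size=n)
    genes = np.array([f"GENE{i}" for i in range(n)], dtype=object)
    genes[rng.random(n) < 0.05] = ""  # intergenic probes have no nearest gene
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chroms,
            "position": positions,
            "gene": genes,
            "blacklisted": False,
        }
    )


# ---------------------------------------------------------------------------
# Beta matrix with planted effects
# ---------------------------------------------------------------------------


def _design_target_samples(design: str, sheet: pd.DataFrame) -> list[str]:
    """Sample ids whose beta is shifted by a planted effect of this design."""
    focal = {
        "asd": ("discordant_asd", "asd_affected"),
        "social": ("discordant_social", "social_affected"),
        "rrbi": ("discordant_rrbi", "rrbi_affected"),
        "communication": ("discordant_communication", "communication_affected"),
    }
    if design in focal:
        group, flag = focal[design]
        sel = (sheet["group"] == group) & sheet[flag]
    elif design == "combined":
        discordant = sheet["group"].str.startswith("discordant_")
        flag_by_group = sheet.apply(
            lambda r: r[
                {
                    "discordant_asd": "asd_affected",
                    "discordant_social": "social_affected",
                    "discordant_rrbi": "rrbi_affected",
                    "discordant_communication": "communication_affected",
                }[r["group"]]
            ]
            if r["group"].startswith("discordant_")
            else False,
            axis=1,
        )
        sel = discordant & flag_by_group
    elif design == "case_control":
        sel = sheet["asd_affected"]
    elif design == "sporadic_vs_familial":
        sel = sheet["familial_class"] == "sporadic"
    else:
        raise ConfigError(f"unknown planting design '{design}'")
    ids = sheet.loc[sel, "sample_id"].tolist()
    if not ids:
        raise ConfigError(f"design '{design}' selects no samples in this cohort")
    return ids


def _simulate_beta(
    config: SimulationConfig,
    sheet: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_probes, n_samples = config.n_probes, len(sheet)
    mix = config.mixture
    component = (rng.random(n_probes) >= mix.weights[0]).astype(int)
    probe_mean = rng.normal(
        np.asarray(mix.locs)[component], np.asarray(mix.sds)[component]
    )
    probe_mean = np.clip(probe_mean, 0.05, 0.95)

    pair_ids = sheet["pair_id"].unique()
    pair_pos = {p: i for i, p in enumerate(pair_ids)}
    pair_of_sample = sheet["pair_id"].map(pair_pos).to_numpy()

    pair_dev = (
        rng.normal(0.0, config.between_pair_sd, size=(n_probes, len(pair_ids)))
        if config.between_pair_sd > 0
        else np.zeros((n_probes, len(pair_ids)))
    )
    noise = (
        rng.normal(0.0, config.within_pair_noise_sd, size=(n_probes, n_samples))
        if config.within_pair_noise_sd > 0
        else np.zeros((n_probes, n_samples))
    )
    beta = probe_mean[:, None] + pair_dev[:, pair_of_sample] + noise

    sample_ids = sheet["sample_id"].tolist()
    col_of = {s: j for j, s in enumerate(sample_ids)}

    for planted in config.planted_dmrs:
        for s in _design_target_samples(planted.design, sheet):
            beta[planted.probe_index, col_of[s]] += planted.delta_beta
    for planted in config.planted_private:
        members = sheet[sheet["pair_id"] == planted.pair_id]
        if members.empty:
            raise ConfigError(f"planted private effect names unknown pair "
                              f"{planted.pair_id!r}")
        affected = members[members[_focal_flag_of(members)].astype(bool)]
        target = (affected if len(affected) == 1 else members.iloc[[0]])
        beta[planted.probe_index, col_of[target["sample_id"].iloc[0]]] += (
            planted.delta_beta
        )

    beta = np.clip(beta, 0.0, 1.0)
    return pd.DataFrame(beta, index=[f"cg{i:08d}" for i in range(n_probes)],
                        columns=sample_ids)


def _focal_flag_of(members: pd.DataFrame) -> str:
    group = members["group"].iloc[0]
    return {
        "discordant_asd": "asd_affected",
        "discordant_social": "social_affected",
        "discordant_rrbi": "rrbi_affected",
        "discordant_communication": "communication_affected",
    }.get(group, "asd_affected")


# ---------------------------------------------------------------------------
# Trait scores
# ---------------------------------------------------------------------------


def _allocate_subscales(total: int) -> dict[str, int]:
    """Decompose a total score into subscale scores within instrument maxima."""
    remaining = total
    out = {}
    for name in ("social", "rrbi", "communication"):
        take = min(SUBSCALE_ITEMS[name], remaining)
        out[name] = take
        remaining -= take
    if remaining:
        raise ConfigError(f"total score {total} exceeds the instrument maximum")
    return out


def simulate_trait_scores(
    config: SimulationConfig,
    sample_sheet: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Integer trait scores from a group-structured latent Gaussian.

    Each domain has a latent ``G = mu(group) + pair + individual`` with the
    pair component shared between twins; the subscale score is the latent
    pushed through the normal CDF and scaled to the item count, so scores
    are bounded integers that track affectedness.  When ``extreme_pair``
    is set, the first ASD-concordant pair is overridden with the configured
    extreme total (subscales filled greedily).
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    sheet = sample_sheet
    n = len(sheet)
    pair_ids = sheet["pair_id"].unique()
    pair_pos = {p: i for i, p in enumerate(pair_ids)}
    pair_of = sheet["pair_id"].map(pair_pos).to_numpy()

    scores = {}
    for domain, k in SUBSCALE_ITEMS.items():
        mu = np.where(sheet[f"{domain}_affected"], _LATENT_AFFECTED, _LATENT_UNAFFECTED)
        latent = (
            mu
            + rng.normal(0.0, _LATENT_PAIR_SD, size=len(pair_ids))[pair_of]
            + rng.normal(0.0, _LATENT_IND_SD, size=n)
        )
        scores[domain] = np.clip(np.rint(k * stats.norm.cdf(latent)), 0, k).astype(int)

    traits = pd.DataFrame({"sample_id": sheet["sample_id"], **scores})

    if config.extreme_pair:
        conc = sheet[sheet["group"] == "concordant_asd"]
        if conc.empty:
            raise ConfigError("extreme_pair requires an ASD-concordant pair")
        extreme_pair_id = conc["pair_id"].iloc[0]
        alloc = _allocate_subscales(config.extreme_pair_score)
        mask = sheet["pair_id"].to_numpy() == extreme_pair_id
        for domain, val in alloc.items():
            traits.loc[mask, domain] = val
        # the extreme pair is by construction the cohort's phenotype
        # outlier: everyone else stays strictly below its score
        cap = max(config.extreme_pair_score - 2, 0)
        order = ("communication", "social", "rrbi")
        for i in np.flatnonzero(~mask):
            excess = int(traits.loc[i, list(SUBSCALE_ITEMS)].sum()) - cap
            for domain in order:
                if excess <= 0:
                    break
                take = min(excess, int(traits.at[i, domain]))
                traits.at[i, domain] -= take
                excess -= take

    traits["total"] = traits[["social", "rrbi", "communication"]].sum(axis=1)
    traits["at_risk"] = traits["total"] >= AT_RISK_CUTOFF
    return traits[["sample_id", "total", "social", "rrbi", "communication", "at_risk"]]


def _plant_trait_loci(
    beta: pd.DataFrame,
    traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Overwrite planted trait-locus rows with score-correlated beta values.

    The residual component is orthogonalised against the standardized
    score in-sample, so the realised Pearson correlation equals the target
    exactly (up to [0,1] clipping, which the mid-range centring avoids).
    """
    n = len(traits)
    for locus in config.planted_trait_loci:
        score = traits[locus.trait].to_numpy(float)
        if np.std(score) == 0:
            warnings.warn(
                f"trait '{locus.trait}' has zero variance; target correlation "
                f"{locus.r} at probe index {locus.probe_index} is unattainable",
                stacklevel=2,
            )
            continue
        z = (score - score.mean()) / score.std()
        e = rng.standard_normal(n)
        resid = e - (e @ z) / (z @ z) * z - e.mean()
        resid = resid - resid.mean()
        sd = resid.std()
        resid = resid / sd if sd > 0 else resid
        x = locus.r * z + np.sqrt(1.0 - locus.r**2) * resid
        row = np.clip(_TRAIT_LOCUS_MEAN + _TRAIT_LOCUS_SD * x, 0.0, 1.0)
        beta.iloc[locus.probe_index] = row


def _apply_extreme_shift(
    beta: pd.DataFrame, sheet: pd.DataFrame, config: SimulationConfig
) -> None:
    if not (config.extreme_pair and config.extreme_probe_indices):
        return
    conc = sheet[sheet["group"] == "concordant_asd"]
    pair_id = conc["pair_id"].iloc[0]
    cols = sheet.loc[sheet["pair_id"] == pair_id, "sample_id"].tolist()
    idx = list(config.extreme_probe_indices)
    block = beta.iloc[idx][cols].to_numpy() + config.extreme_shift
    beta.loc[beta.index[idx], cols] = np.clip(block, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Intensities and artifacts
# ---------------------------------------------------------------------------


def _derive_signals(
    beta: pd.DataFrame, rng: np.random.Generator
) -> SignalSet:
    total = rng.lognormal(
        _MEAN_LOG_TOTAL_SIGNAL, _SD_LOG_TOTAL_SIGNAL, size=beta.shape
    )
    b = beta.to_numpy()
    meth = pd.DataFrame(b * total, index=beta.index, columns=beta.columns)
    unmeth = pd.DataFrame((1.0 - b) * total, index=beta.index, columns=beta.columns)
    detp = pd.DataFrame(
        np.zeros(beta.shape), index=beta.index, columns=beta.columns
    )
    return SignalSet(meth, unmeth, detp)


def inject_artifacts(
    signals: SignalSet,
    manifest: pd.DataFrame,
    config: SimulationConfig,
    sample_sheet: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    protected: set[int] | None = None,
) -> tuple[SignalSet, pd.DataFrame]:
    """Detection failures, SNP-driven trimodal probes and blacklist flags.

    Planted probes (``protected``) never receive artifacts, so ground truth
    stays recoverable.  SNP probes get genotype-like beta values shared
    within each MZ pair (modes at 0, 0.5, 1 within +/-0.1); detection
    failures draw p above 0.05 at the configured probe-by-sample rate;
    blacklist flags are set on the manifest only.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    protected = set(protected or ())
    n_probes, n_samples = signals.shape
    n_blacklist, n_snp = config.blacklist_count, config.snp_artifact_count
    if n_blacklist + n_snp > n_probes - len(protected):
        raise ConfigError("artifact probe counts exceed available probes")

    meth = signals.methylated.to_numpy().copy()
    unmeth = signals.unmethylated.to_numpy().copy()

    # detection p: confident baseline, failures strictly above 0.05
    detp = rng.uniform(0.0, 0.01, size=(n_probes, n_samples))
    if config.detection_failure_rate > 0:
        fail = rng.random((n_probes, n_samples)) < config.detection_failure_rate
        if protected:
            fail[list(protected), :] = False
        detp[fail] = rng.uniform(0.051, 1.0, size=int(fail.sum()))

    free = np.array(sorted(set(range(n_probes)) - protected))
    chosen = rng.choice(free, size=n_snp + n_blacklist, replace=False)
    snp_idx = np.sort(chosen[:n_snp])
    blacklist_idx = np.sort(chosen[n_snp:])

    # SNP probes: per-pair genotype under HWE; both twins share it
    if snp_idx.size:
        pair_ids = sample_sheet["pair_id"].unique()
        pair_pos = {p: i for i, p in enumerate(pair_ids)}
        pair_of = sample_sheet["pair_id"].map(pair_pos).to_numpy()
        maf = rng.uniform(0.2, 0.5, size=snp_idx.size)
        genotype = rng.binomial(2, maf[:, None], size=(snp_idx.size, len(pair_ids)))
        wobble = np.clip(
            rng.normal(0.0, 0.03, size=(snp_idx.size, n_samples)), -0.09, 0.09
        )
        snp_beta = np.clip(genotype[:, pair_of] / 2.0 + wobble, 0.0, 1.0)
        total = meth[snp_idx] + unmeth[snp_idx]
        meth[snp_idx] = snp_beta * total
        unmeth[snp_idx] = (1.0 - snp_beta) * total

    out_manifest = manifest.copy()
    out_manifest["blacklisted"] = False
    out_manifest.iloc[
        blacklist_idx, out_manifest.columns.get_loc("blacklisted")
    ] = True

    out = SignalSet(
        pd.DataFrame(meth, index=signals.probes, columns=signals.samples),
        pd.DataFrame(unmeth, index=signals.probes, columns=signals.samples),
        pd.DataFrame(detp, index=signals.probes, columns=signals.samples),
    )
    return out, out_manifest


# ---------------------------------------------------------------------------
# Truth table and top-level driver
# ---------------------------------------------------------------------------


def _build_truth(config: SimulationConfig, probe_ids: list[str]) -> pd.DataFrame:
    rows = []
    for p in config.planted_dmrs:
        rows.append(
            {"probe_id": probe_ids[p.probe_index], "mechanism": "dmr",
             "effect": p.delta_beta, "design": p.design, "pair_id": "", "trait": ""}
        )
    for p in config.planted_private:
        rows.append(
            {"probe_id": probe_ids[p.probe_index], "mechanism": "private",
             "effect": p.delta_beta, "design": "", "pair_id": p.pair_id, "trait": ""}
        )
    for p in config.planted_trait_loci:
        rows.append(
            {"probe_id": probe_ids[p.probe_index], "mechanism": "trait",
             "effect": p.r, "design": "", "pair_id": "", "trait": p.trait}
        )
    return pd.DataFrame(
        rows, columns=["probe_id", "mechanism", "effect", "design", "pair_id", "trait"]
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a complete study: signals, manifest, sheet, traits, truth.

    Deterministic for a fixed seed: every table is byte-identical across
    calls with the same configuration.
    """
    config.validate()
    streams = _streams(config.seed)

    sheet = make_sample_sheet(config, streams["sheet"])
    manifest = make_manifest(config, streams["manifest"])
    beta = _simulate_beta(config, sheet, streams["beta"])
    traits = simulate_trait_scores(config, sheet, streams["traits"])
    _plant_trait_loci(beta, traits, config, streams["trait_loci"])
    _apply_extreme_shift(beta, sheet, config)

    signals = _derive_signals(beta, streams["signal"])
    protected = set(config.planted_indices()) | set(config.extreme_probe_indices)
    signals, manifest = inject_artifacts(
        signals, manifest, config, sheet, streams["artifacts"], protected
    )
    truth = _build_truth(config, manifest["probe_id"].tolist())
    return Cohort(
        signals=signals,
        manifest=manifest,
        sample_sheet=sheet,
        traits=traits,
        truth=truth,
        beta_true=beta,
    )
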