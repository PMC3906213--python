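"""Configuration objects for the cohort simulator and the pipeline driver.

The simulator defaults describe the cohort the analyses were designed for:
27,578 CpG probes with a bimodal beta-value distribution, 50 MZ twin pairs
(100 individuals) split into ASD-discordant (6 pairs), ASD-concordant (5),
trait-discordant (social 9, RRBI 9, communication 8) and unaffected
concordant (13) groups, with realistic probe artifacts (detection failures,
a 2,923-probe blacklist, SNP-driven trimodal probes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .exceptions import ConfigError

#: Allowed planting designs for differential effects.
DMR_DESIGNS = (
    "asd",
    "social",
    "rrbi",
    "communication",
    "combined",
    "case_control",
    "sporadic_vs_familial",
)

#: Trait score columns (total plus the three subscales).
TRAITS = ("total", "social", "rrbi", "communication")

#: CAST-style instrument structure: 31 items in subscales of 12 / 7 / 12.
SUBSCALE_ITEMS = {"social": 12, "rrbi": 7, "communication": 12}
MAX_TOTAL_SCORE = 31
AT_RISK_CUTOFF = 15

#: Sample-sheet group labels.
GROUPS = (
    "discordant_asd",
    "concordant_asd",
    "discordant_social",
    "discordant_rrbi",
    "discordant_communication",
    "concordant_unaffected",
)


@dataclass(frozen=True)
class BimodalMixture:
    """Two-component Gaussian mixture on the beta scale.

    Promoter-targeted arrays put most probes near full unmethylation, a
    second mode near full methylation, and little mass in between.
    """

    locs: tuple[float, float] = (0.15, 0.80)
    sds: tuple[float, float] = (0.06, 0.07)
    weights: tuple[float, float] = (0.60, 0.40)

    def validate(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigError(f"mixture weights must sum to 1, got {self.weights}")
        if not all(0.0 < l < 1.0 for l in self.locs):
            raise ConfigError(f"mixture locations must lie in (0, 1), got {self.locs}")
        if not all(s > 0 for s in self.sds):
            raise ConfigError("mixture spreads must be positive")


@dataclass(frozen=True)
class PlantedDmr:
    """A consistent within-design differential effect at one probe.

    ``delta_beta`` is added to the affected members of every pair (or to the
    case group) of the target design, so the affected-minus-unaffected
    difference equals ``delta_beta`` before noise and clipping.
    """

    probe_index: int
    design: str
    delta_beta: float


@dataclass(frozen=True)
class PlantedPrivate:
    """A family-private large effect: one probe, one pair."""

    probe_index: int
    pair_id: str
    delta_beta: float


@dataclass(frozen=True)
class PlantedTraitLocus:
    """A probe whose methylation correlates with a quantitative trait score."""

    probe_index: int
    trait: str
    r: float


@dataclass
class SimulationConfig:
    seed: int
    n_probes: int = 27578
    n_pairs_discordant_asd: int = 6
    n_pairs_concordant_asd: int = 5
    n_pairs_discordant_social: int = 9
    n_pairs_discordant_rrbi: int = 9
    n_pairs_discordant_communication: int = 8
    n_pairs_concordant_unaffected: int = 13
    mixture: BimodalMixture = field(default_factory=BimodalMixture)
    #: Pair-level deviation of the shared twin baseline around the probe mean.
    between_pair_sd: float = 0.03
    #: Independent per-individual noise on the beta scale.
    within_pair_noise_sd: float = 0.02
    planted_dmrs: tuple[PlantedDmr, ...] = ()
    planted_private: tuple[PlantedPrivate, ...] = ()
    planted_trait_loci: tuple[PlantedTraitLocus, ...] = ()
    #: Per probe-by-sample probability of a detection failure (p drawn > 0.05).
    detection_failure_rate: float = 4.3e-4
    #: None scales the array-survey proportion (2,923 of 27,578) to n_probes.
    n_blacklist: int | None = None
    #: None scales the default SNP-artifact load (25 of 27,578) to n_probes.
    n_snp_artifact: int | None = None
    x_probe_frac: float = 0.031
    y_probe_frac: float = 0.004
    extreme_pair: bool = False
    extreme_pair_score: int = 29
    extreme_probe_indices: tuple[int, ...] = ()
    extreme_shift: float = 0.30

    # -- derived -----------------------------------------------------------

    @property
    def blacklist_count(self) -> int:
        if self.n_blacklist is not None:
            return self.n_blacklist
        return int(round(self.n_probes * 2923 / 27578))

    @property
    def snp_artifact_count(self) -> int:
        if self.n_snp_artifact is not None:
            return self.n_snp_artifact
        return int(round(self.n_probes * 25 / 27578))

    @property
    def group_pair_counts(self) -> dict[str, int]:
        return {
            "discordant_asd": self.n_pairs_discordant_asd,
            "concordant_asd": self.n_pairs_concordant_asd,
            "discordant_social": self.n_pairs_discordant_social,
            "discordant_rrbi": self.n_pairs_discordant_rrbi,
            "discordant_communication": self.n_pairs_discordant_communication,
            "concordant_unaffected": self.n_pairs_concordant_unaffected,
        }

    @property
    def n_pairs(self) -> int:
        return sum(self.group_pair_counts.values())

    @property
    def n_samples(self) -> int:
        return 2 * self.n_pairs

    def planted_indices(self) -> dict[int, str]:
        """Map planted probe index -> mechanism, rejecting cross-mechanism
        overlaps.

        One probe may carry several private effects (in different pairs —
        the recurrent family-private pattern), but never two mechanisms,
        and never two DMR or trait plantings.
        """
        seen: dict[int, str] = {}
        private_pairs: dict[int, set[str]] = {}
        for mech, indices in (
            ("dmr", [p.probe_index for p in self.planted_dmrs]),
            ("private", [p.probe_index for p in self.planted_private]),
            ("trait", [p.probe_index for p in self.planted_trait_loci]),
        ):
            for idx in indices:
                if idx in seen and not (mech == "private" == seen[idx]):
                    raise ConfigError(
                        f"probe index {idx} planted under both "
                        f"'{seen[idx]}' and '{mech}' mechanisms"
                    )
                seen[idx] = mech
        for p in self.planted_private:
            pairs = private_pairs.setdefault(p.probe_index, set())
            if p.pair_id in pairs:
                raise ConfigError(
                    f"probe index {p.probe_index} planted twice in pair "
                    f"{p.pair_id!r}"
                )
            pairs.add(p.pair_id)
        return seen

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ConfigError("n_probes must be positive")
        if any(n < 0 for n in self.group_pair_counts.values()):
            raise ConfigError("pair counts must be non-negative")
        if self.n_pairs == 0:
            raise ConfigError("at least one twin pair is required")
        self.mixture.validate()
        if self.between_pair_sd < 0 or self.within_pair_noise_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        if not 0.0 <= self.detection_failure_rate <= 1.0:
            raise ConfigError("detection_failure_rate must lie in [0, 1]")
        if self.blacklist_count < 0 or self.snp_artifact_count < 0:
            raise ConfigError("artifact probe counts must be non-negative")
        if self.blacklist_count + self.snp_artifact_count > self.n_probes:
            raise ConfigError("artifact probe counts exceed n_probes")
        for p in self.planted_dmrs:
            if p.design not in DMR_DESIGNS:
                raise ConfigError(
                    f"unknown planting design '{p.design}'; allowed: {DMR_DESIGNS}"
                )
            if not -1.0 < p.delta_beta < 1.0:
                raise ConfigError(f"planted delta-beta {p.delta_beta} outside (-1, 1)")
        for q in self.planted_private:
            if not -1.0 < q.delta_beta < 1.0:
                raise ConfigError(f"planted delta-beta {q.delta_beta} outside (-1, 1)")
        for t in self.planted_trait_loci:
            if t.trait not in TRAITS:
                raise ConfigError(f"unknown trait '{t.trait}'; allowed: {TRAITS}")
            if not -1.0 < t.r < 1.0:
                raise ConfigError(f"target correlation {t.r} outside (-1, 1)")
        planted = self.planted_indices()
        bad = [i for i in planted if not 0 <= i < self.n_probes]
        if bad:
            raise ConfigError(f"planted probe indices out of range: {bad}")
        bad = [i for i in self.extreme_probe_indices if not 0 <= i < self.n_probes]
        if bad:
            raise ConfigError(f"extreme probe indices out of range: {bad}")
        if self.extreme_pair:
            if self.n_pairs_concordant_asd < 1:
                raise ConfigError(
                    "extreme_pair requires at least one ASD-concordant pair"
                )
            if not 0 <= self.extreme_pair_score <= MAX_TOTAL_SCORE:
                raise ConfigError(
                    f"extreme_pair_score must lie in [0, {MAX_TOTAL_SCORE}]"
                )
        if not 0.0 <= self.x_probe_frac + self.y_probe_frac < 1.0:
            raise ConfigError("sex-probe fractions must leave room for autosomes")


# ---------------------------------------------------------------------------
# Pipeline run configuration
# ---------------------------------------------------------------------------

#: Analysis designs the driver knows how to run.
RUN_DESIGNS = ("asd", "social", "rrbi", "communication", "combined")


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    simulation: SimulationConfig | None = None
    input_paths: dict[str, str] | None = None
    designs: tuple[str, ...] = RUN_DESIGNS
    detection_threshold: float = 0.05
    family_threshold: float = 0.15
    top_k: int = 50
    log_level: str = "INFO"
    #: fields that fell back to defaults during parsing (for validate-config)
    defaulted: tuple[str, ...] = ()

    def validate(self) -> list[str]:
        """Return a list of violations (empty when valid)."""
        problems: list[str] = []
        if not 0.0 < self.detection_threshold <= 1.0:
            problems.append(
                f"detection_threshold {self.detection_threshold} outside (0, 1]"
            )
        if not 0.0 < self.family_threshold < 1.0:
            problems.append(f"family_threshold {self.family_threshold} outside (0, 1)")
        if self.top_k < 1:
            problems.append("top_k must be >= 1")
        for d in self.designs:
            if d not in RUN_DESIGNS:
                problems.append(f"unknown design '{d}'; allowed: {RUN_DESIGNS}")
        if self.simulation is None and not self.input_paths:
            problems.append("either a simulation block or input paths are required")
        if self.simulation is not None:
            if self.seed is None:
                problems.append("seed is required when simulation is requested")
            try:
                self.simulation.validate()
            except ConfigError as exc:
                problems.append(str(exc))
        return problems


_SIM_SCALAR_FIELDS = (
    "n_probes",
    "n_pairs_discordant_asd",
    "n_pairs_concordant_asd",
    "n_pairs_discordant_social",
    "n_pairs_discordant_rrbi",
    "n_pairs_discordant_communication",
    "n_pairs_concordant_unaffected",
    "between_pair_sd",
    "within_pair_noise_sd",
    "detection_failure_rate",
    "n_blacklist",
    "n_snp_artifact",
    "x_probe_frac",
    "y_probe_frac",
    "extreme_pair",
    "extreme_pair_score",
    "extreme_shift",
)


def simulation_config_from_dict(data: dict, seed: int) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML mapping."""
    kwargs: dict = {"seed": seed}
    for name in _SIM_SCALAR_FIELDS:
        if name in data:
            kwargs[name] = data[name]
    if "mixture" in data:
        m = data["mixture"]
        kwargs["mixture"] = BimodalMixture(
            locs=tuple(m.get("locs", BimodalMixture.locs)),
            sds=tuple(m.get("sds", BimodalMixture.sds)),
            weights=tuple(m.get("weights", BimodalMixture.weights)),
        )
    kwargs["planted_dmrs"] = tuple(
        PlantedDmr(int(d["probe_index"]), str(d["design"]), float(d["delta_beta"]))
        for d in data.get("planted_dmrs", [])
    )
    kwargs["planted_private"] = tuple(
        PlantedPrivate(int(d["probe_index"]), str(d["pair_id"]), float(d["delta_beta"]))
        for d in data.get("planted_private", [])
    )
    kwargs["planted_trait_loci"] = tuple(
        PlantedTraitLocus(int(d["probe_index"]), str(d["trait"]), float(d["r"]))
        for d in data.get("planted_trait_loci", [])
    )
    kwargs["extreme_probe_indices"] = tuple(data.get("extreme_probe_indices", ()))
    return SimulationConfig(**kwargs)


def load_run_config(
    path: str | Path,
    *,
    overrides: dict | None = None,
) -> RunConfig:
    """Parse a YAML run configuration; CLI flag overrides win over file values."""
    path = Path(path)
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    overrides = {k: v for k, v in (overrides or {}).items() if v is not None}
    data = {**data, **overrides}

    defaulted = []
    for name, default in (
        ("designs", list(RUN_DESIGNS)),
        ("detection_threshold", 0.05),
        ("family_threshold", 0.15),
        ("top_k", 50),
        ("log_level", "INFO"),
    ):
        if name not in data:
            data[name] = default
            defaulted.append(name)

    seed = data.get("seed")
    sim = None
    if "simulation" in data:
        if seed is None:
            raise ConfigError("seed is required when a simulation block is present")
        sim = simulation_config_from_dict(data["simulation"] or {}, int(seed))
    if seed is None:
        raise ConfigError("seed is required")
    if "outdir" not in data:
        raise ConfigError("outdir is required")

    return RunConfig(
        seed=int(seed),
        outdir=Path(data["outdir"]),
        simulation=sim,
        input_paths=data.get("inputs"),
        designs=tuple(data["designs"]),
        detection_threshold=float(data["detection_threshold"]),
        family_threshold=float(data["family_threshold"]),
        top_k=int(data["top_k"]),
        log_level=str(data["log_level"]),
        defaulted=tuple(defaulted),
    )
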