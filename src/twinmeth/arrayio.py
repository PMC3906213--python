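"""Readers and writers for every tabular format the pipeline touches.

All formats are header-carrying TSV/CSV; column dictionaries live in
``docs/formats.md``.  Readers validate on load and reject inconsistent
indexing outright rather than silently intersecting probe or sample sets.
Numeric round-trips are lossless to 6 decimal places.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import PairingError, ValidationError

ALLOWED_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
SEX_CHROMOSOMES = ("X", "Y")

_FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# SignalSet
# ---------------------------------------------------------------------------


@dataclass
class SignalSet:
    """Probe-by-sample methylated / unmethylated intensities plus detection p.

    The three layers share one probe index (rows) and one sample index
    (columns); construction enforces the alignment and non-negativity.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        m, u, d = self.methylated, self.unmethylated, self.detection_p
        for name, layer in (("unmethylated", u), ("detection_p", d)):
            if not m.index.equals(layer.index) or not m.columns.equals(layer.columns):
                raise ValidationError(
                    f"layer '{name}' is indexed differently from 'methylated'"
                )
        if m.index.has_duplicates:
            dups = m.index[m.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        for name, layer in (("methylated", m), ("unmethylated", u)):
            vals = layer.to_numpy()
            if (vals < 0).any():
                i, j = np.argwhere(vals < 0)[0]
                raise ValidationError(
                    f"negative {name} signal at probe "
                    f"{layer.index[i]!r}, sample {layer.columns[j]!r}"
                )
        dvals = d.to_numpy()
        if ((dvals < 0) | (dvals > 1)).any():
            i, j = np.argwhere((dvals < 0) | (dvals > 1))[0]
            raise ValidationError(
                f"detection p outside [0, 1] at probe "
                f"{d.index[i]!r}, sample {d.columns[j]!r}"
            )

    @property
    def probes(self) -> pd.Index:
        return self.methylated.index

    @property
    def samples(self) -> pd.Index:
        return self.methylated.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.methylated.shape

    def loc_probes(self, probe_ids) -> "SignalSet":
        return SignalSet(
            self.methylated.loc[probe_ids],
            self.unmethylated.loc[probe_ids],
            self.detection_p.loc[probe_ids],
        )


def write_signals(signals: SignalSet, path: str | Path) -> None:
    """Write a SignalSet as one wide TSV: per sample a .meth/.unmeth/.detp triplet."""
    cols = {}
    for s in signals.samples:
        cols[f"{s}.meth"] = signals.methylated[s]
        cols[f"{s}.unmeth"] = signals.unmethylated[s]
        cols[f"{s}.detp"] = signals.detection_p[s]
    wide = pd.DataFrame(cols, index=signals.probes)
    wide.index.name = "probe_id"
    wide.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_signals(path: str | Path) -> SignalSet:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"signal file not found: {path}")
    wide = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in wide.columns:
        raise ValidationError(f"{path}: missing 'probe_id' column")
    dup = wide["probe_id"][wide["probe_id"].duplicated()]
    if not dup.empty:
        # +2: one for the header line, one for 1-based numbering
        lines = (dup.index + 2).tolist()
        raise ValidationError(
            f"{path}: duplicate probe id(s) {sorted(dup.unique())[:5]} "
            f"at line(s) {lines[:5]}"
        )
    wide = wide.set_index("probe_id")
    samples, layers = [], {"meth": [], "unmeth": [], "detp": []}
    for col in wide.columns:
        if "." not in col:
            raise ValidationError(f"{path}: unrecognised column '{col}'")
        sample, layer = col.rsplit(".", 1)
        if layer not in layers:
            raise ValidationError(f"{path}: unrecognised column '{col}'")
        if sample not in samples:
            samples.append(sample)
        layers[layer].append(sample)
    for layer, present in layers.items():
        missing = [s for s in samples if s not in present]
        if missing:
            raise ValidationError(
                f"{path}: missing '{layer}' layer for sample(s) {missing[:5]}"
            )
    bad = wide.columns[wide.isna().any()]
    if len(bad):
        rows = wide.index[wide[bad[0]].isna()].tolist()
        raise ValidationError(
            f"{path}: missing values in column '{bad[0]}' (probe {rows[0]!r}); "
            "missing signal values are not permitted"
        )

    def layer_frame(suffix: str) -> pd.DataFrame:
        frame = wide[[f"{s}.{suffix}" for s in samples]].copy()
        frame.columns = samples
        return frame.astype(float)

    try:
        return SignalSet(layer_frame("meth"), layer_frame("unmeth"), layer_frame("detp"))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["probe_id", "chromosome", "position", "gene", "blacklisted"]


def validate_manifest(manifest: pd.DataFrame, context: str = "manifest") -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"{context}: missing column(s) {missing}")
    if manifest["probe_id"].duplicated().any():
        dups = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"]
        raise ValidationError(f"{context}: duplicate probe id(s) {dups.tolist()[:5]}")
    bad = ~manifest["chromosome"].astype(str).isin(ALLOWED_CHROMOSOMES)
    if bad.any():
        vals = manifest.loc[bad, "chromosome"].unique().tolist()
        raise ValidationError(
            f"{context}: chromosome label(s) {vals[:5]} not in "
            f"{{1..22, X, Y}}"
        )
    if (manifest["position"] <= 0).any():
        probe = manifest.loc[manifest["position"] <= 0, "probe_id"].iloc[0]
        raise ValidationError(f"{context}: non-positive position at probe {probe!r}")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest)
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(
        path,
        sep="\t",
        dtype={"probe_id": str, "chromosome": str, "gene": str},
        keep_default_na=False,
        na_values=[],
    )
    manifest["position"] = manifest["position"].astype(int)
    manifest["blacklisted"] = manifest["blacklisted"].map(
        {"True": True, "False": False, True: True, False: False}
    )
    if manifest["blacklisted"].isna().any():
        raise ValidationError(f"{path}: 'blacklisted' must be True/False")
    validate_manifest(manifest, context=str(path))
    return manifest


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = [
    "sample_id",
    "pair_id",
    "member",
    "sex",
    "group",
    "asd_affected",
    "social_affected",
    "rrbi_affected",
    "communication_affected",
    "familial_class",
]

_FOCAL_FLAG = {
    "discordant_asd": "asd_affected",
    "discordant_social": "social_affected",
    "discordant_rrbi": "rrbi_affected",
    "discordant_communication": "communication_affected",
}

_FLAG_COLUMNS = [
    "asd_affected",
    "social_affected",
    "rrbi_affected",
    "communication_affected",
]


def validate_sample_sheet(sheet: pd.DataFrame, context: str = "sample sheet") -> None:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"{context}: missing column(s) {missing}")
    if sheet["sample_id"].duplicated().any():
        raise PairingError(f"{context}: duplicate sample ids")
    counts = sheet["pair_id"].value_counts()
    bad = counts[counts != 2]
    if not bad.empty:
        raise PairingError(
            f"{context}: pair(s) {bad.index.tolist()[:5]} do not occur exactly twice"
        )
    for pair_id, members in sheet.groupby("pair_id"):
        group = members["group"].iloc[0]
        if members["group"].nunique() != 1:
            raise PairingError(f"{context}: pair {pair_id!r} spans two groups")
        focal = _FOCAL_FLAG.get(group)
        if focal is not None:
            n_affected = int(members[focal].sum())
            if n_affected != 1:
                raise PairingError(
                    f"{context}: discordant pair {pair_id!r} has {n_affected} "
                    f"affected members for its focal domain ({focal}); expected 1"
                )
        elif group in ("concordant_asd", "concordant_unaffected"):
            for col in _FLAG_COLUMNS:
                if members[col].nunique() != 1:
                    raise PairingError(
                        f"{context}: concordant pair {pair_id!r} has "
                        f"mismatched '{col}' flags"
                    )


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet)
    sheet[SHEET_COLUMNS].to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(
        path,
        dtype={"sample_id": str, "pair_id": str, "member": str, "sex": str,
               "group": str, "familial_class": str},
        keep_default_na=False,
        na_values=[],
    )
    for col in _FLAG_COLUMNS:
        if col in sheet.columns:
            sheet[col] = sheet[col].map(
                {"True": True, "False": False, True: True, False: False}
            )
    validate_sample_sheet(sheet, context=str(path))
    return sheet


# ---------------------------------------------------------------------------
# Trait scores
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = ["sample_id", "total", "social", "rrbi", "communication", "at_risk"]


def validate_trait_table(traits: pd.DataFrame, context: str = "trait table") -> None:
    from .config import AT_RISK_CUTOFF, MAX_TOTAL_SCORE, SUBSCALE_ITEMS

    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise ValidationError(f"{context}: missing column(s) {missing}")
    for col, top in (
        ("total", MAX_TOTAL_SCORE),
        ("social", SUBSCALE_ITEMS["social"]),
        ("rrbi", SUBSCALE_ITEMS["rrbi"]),
        ("communication", SUBSCALE_ITEMS["communication"]),
    ):
        vals = traits[col]
        if ((vals < 0) | (vals > top)).any():
            raise ValidationError(f"{context}: '{col}' scores outside [0, {top}]")
    subtotal = traits[["social", "rrbi", "communication"]].sum(axis=1)
    if (subtotal != traits["total"]).any():
        raise ValidationError(f"{context}: subscales do not sum to total")
    if ((traits["total"] >= AT_RISK_CUTOFF) != traits["at_risk"]).any():
        raise ValidationError(
            f"{context}: at_risk flag inconsistent with total >= {AT_RISK_CUTOFF}"
        )


def write_trait_table(traits: pd.DataFrame, path: str | Path) -> None:
    validate_trait_table(traits)
    traits[TRAIT_COLUMNS].to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    traits = pd.read_csv(path, dtype={"sample_id": str})
    traits["at_risk"] = traits["at_risk"].map(
        {"True": True, "False": False, True: True, False: False}
    )
    validate_trait_table(traits, context=str(path))
    return traits


# ---------------------------------------------------------------------------
# Truth table (simulator ground truth)
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["probe_id", "mechanism", "effect", "design", "pair_id", "trait"]


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(
        path,
        sep="\t",
        dtype={"probe_id": str, "mechanism": str, "design": str,
               "pair_id": str, "trait": str},
        keep_default_na=False,
        na_values=[],
    )
    truth["effect"] = truth["effect"].astype(float)
    return truth


# ---------------------------------------------------------------------------
# Plain probe-by-sample matrices (beta / transformed values)
# ---------------------------------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", dtype={"probe_id": str}).set_index("probe_id")
    return matrix.astype(float)


# ---------------------------------------------------------------------------
# Ranked DMR tables and BED export
# ---------------------------------------------------------------------------

#: Leading columns mirror the published table layout:
#: rank, probe, gene, chromosome, position, mean delta-beta, p-value.
DMR_TABLE_COLUMNS = [
    "rank",
    "probe_id",
    "gene",
    "chromosome",
    "position",
    "mean_delta_beta",
    "p_value",
    "t",
    "p_rank",
    "magnitude_rank",
    "combined_score",
    "bonferroni_significant",
    "design",
]


def write_dmr_table(records: pd.DataFrame, path: str | Path) -> None:
    """Ranked DMR table as TSV; empty input yields a header-only file."""
    out = records.copy()
    if "rank" not in out.columns and "combined_rank" in out.columns:
        out = out.rename(columns={"combined_rank": "rank"})
    for col in DMR_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = pd.Series(dtype=object)
    out[DMR_TABLE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bed(
    records: pd.DataFrame, manifest: pd.DataFrame, path: str | Path
) -> None:
    """One 0-based half-open interval per CpG: (position-1, position).

    Name is the probe id; score is |mean delta-beta| scaled to 0-1000.
    """
    anno = manifest.set_index("probe_id")
    with open(path, "w") as fh:
        for _, row in records.iterrows():
            probe = row["probe_id"]
            chrom = anno.loc[probe, "chromosome"]
            pos = int(anno.loc[probe, "position"])
            score = int(round(min(abs(float(row["mean_delta_beta"])), 1.0) * 1000))
            fh.write(f"chr{chrom}\t{pos - 1}\t{pos}\t{probe}\t{score}\n")
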