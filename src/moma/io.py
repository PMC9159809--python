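"""Tabular input/output and the shared in-memory data model.

All on-disk tables are tab-separated UTF-8 text with a header row; matrices
carry feature identifiers in the first column and sample identifiers in the
header.  Sample roles (tumour vs. non-malignant) and the tumour↔normal
pairing live in side tables rather than being encoded in sample names.
Floating-point values are written with a canonical ``%.10g`` format so that
write→read→write round-trips are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TUMOUR = "tumour"
NON_MALIGNANT = "non_malignant"
_ROLES = (TUMOUR, NON_MALIGNANT)

# 17 significant digits always round-trip float64 exactly, so write→read
# restores values bit-for-bit and rewriting is byte-stable
FLOAT_FMT = "%.17g"

__all__ = [
    "ExpressionMatrix",
    "MethylationData",
    "CopyNumberCalls",
    "ClinicalTable",
    "Config",
    "read_expression",
    "write_expression",
    "read_methylation",
    "write_methylation",
    "read_cn",
    "write_cn",
    "read_clinical",
    "write_clinical",
    "read_target_map",
    "write_target_map",
    "read_id_set",
    "write_id_set",
    "load_config",
    "save_config",
    "TUMOUR",
    "NON_MALIGNANT",
]


class OmicsIOError(ValueError):
    """Raised on malformed or invariant-violating input tables."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Non-negative feature × sample abundances (FPKM or RPM).

    Parameters
    ----------
    values : pandas.DataFrame
        Features in rows, samples in columns; all entries finite and >= 0.
    sample_role : pandas.Series
        Maps every sample to ``"tumour"`` or ``"non_malignant"``.
    pairing : dict or None
        Optional injective map from tumour sample id to its matched
        non-malignant sample id.
    """

    values: pd.DataFrame
    sample_role: pd.Series
    pairing: dict[str, str] | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise OmicsIOError(f"duplicate feature ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise OmicsIOError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise OmicsIOError(
                f"missing value at feature {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise OmicsIOError(
                f"non-finite value at feature {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise OmicsIOError(
                f"negative value {arr[i, j]} at feature {v.index[i]!r}, "
                f"sample {v.columns[j]!r}"
            )
        missing = [s for s in v.columns if s not in self.sample_role.index]
        if missing:
            raise OmicsIOError(f"samples missing from role table: {missing}")
        bad = self.sample_role[~self.sample_role.isin(_ROLES)]
        if len(bad):
            raise OmicsIOError(f"invalid roles: {bad.to_dict()}")
        self.sample_role = self.sample_role.reindex(v.columns)
        if self.pairing is not None:
            vals = list(self.pairing.values())
            if len(set(vals)) != len(vals):
                raise OmicsIOError("pairing is not injective")
            for t, n in self.pairing.items():
                if self.sample_role.get(t) != TUMOUR:
                    raise OmicsIOError(f"pairing key {t!r} is not a tumour sample")
                if self.sample_role.get(n) != NON_MALIGNANT:
                    raise OmicsIOError(
                        f"pairing value {n!r} is not a non-malignant sample"
                    )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumour_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_role[s] == TUMOUR]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_role[s] == NON_MALIGNANT]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.sample_role.equals(other.sample_role)
            and (self.pairing or {}) == (other.pairing or {})
        )


@dataclass
class MethylationData:
    """Probe × sample β values in [0, 1] with probe→gene annotation."""

    beta: pd.DataFrame
    probe_gene: pd.Series
    probe_region: pd.Series
    sample_role: pd.Series

    def __post_init__(self) -> None:
        b = self.beta
        arr = b.to_numpy(dtype=float)
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise OmicsIOError(
                f"missing beta at probe {b.index[i]!r}, sample {b.columns[j]!r}"
            )
        if (arr < 0).any() or (arr > 1).any():
            i, j = np.argwhere((arr < 0) | (arr > 1))[0]
            raise OmicsIOError(
                f"beta {arr[i, j]} outside [0, 1] at probe {b.index[i]!r}, "
                f"sample {b.columns[j]!r}"
            )
        unannotated = [p for p in b.index if p not in self.probe_gene.index]
        if unannotated:
            raise OmicsIOError(f"probes missing from annotation: {unannotated}")
        missing = [s for s in b.columns if s not in self.sample_role.index]
        if missing:
            raise OmicsIOError(f"samples missing from role table: {missing}")
        self.sample_role = self.sample_role.reindex(b.columns)
        self.probe_gene = self.probe_gene.reindex(b.index)
        self.probe_region = self.probe_region.reindex(b.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.probe_gene:
            seen.setdefault(g)
        return list(seen)

    def probes_for(self, gene: str) -> list[str]:
        return list(self.probe_gene.index[self.probe_gene == gene])

    @property
    def tumour_samples(self) -> list[str]:
        return [s for s in self.beta.columns if self.sample_role[s] == TUMOUR]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.beta.columns if self.sample_role[s] == NON_MALIGNANT]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationData):
            return NotImplemented
        return (
            self.beta.equals(other.beta)
            and self.probe_gene.equals(other.probe_gene)
            and self.probe_region.equals(other.probe_region)
            and self.sample_role.equals(other.sample_role)
        )


@dataclass
class CopyNumberCalls:
    """Gene × sample discrete copy-number categories in {-2, -1, 0, 1, 2}."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.calls
        arr = c.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise OmicsIOError("missing copy-number call")
        if not np.isin(arr, [-2, -1, 0, 1, 2]).all():
            i, j = np.argwhere(~np.isin(arr, [-2, -1, 0, 1, 2]))[0]
            raise OmicsIOError(
                f"copy-number call {arr[i, j]} outside {{-2..2}} at gene "
                f"{c.index[i]!r}, sample {c.columns[j]!r}"
            )
        self.calls = c.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CopyNumberCalls):
            return NotImplemented
        return self.calls.equals(other.calls)


@dataclass
class ClinicalTable:
    """Per-patient overall survival: time in days plus event indicator."""

    table: pd.DataFrame  # index: sample; columns: os_days, event

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise OmicsIOError("duplicate sample ids in clinical table")
        for col in ("os_days", "event"):
            if col not in t.columns:
                raise OmicsIOError(f"clinical table missing column {col!r}")
            if t[col].isna().any():
                raise OmicsIOError(f"missing value in clinical column {col!r}")
        if (t["os_days"] < 0).any():
            bad = t.index[t["os_days"] < 0][0]
            raise OmicsIOError(f"negative survival time for sample {bad!r}")
        if not t["event"].isin([0, 1]).all():
            bad = t.index[~t["event"].isin([0, 1])][0]
            raise OmicsIOError(f"event indicator not in {{0,1}} for sample {bad!r}")
        self.table = t.assign(
            os_days=t["os_days"].astype(float), event=t["event"].astype(int)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClinicalTable):
            return NotImplemented
        return self.table.equals(other.table)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Every analysis threshold, defaulting to the published values.

    Attributes
    ----------
    fence_multiplier : float
        IQR multiplier of the Tukey fences (1.5).
    log2_pseudocount : float
        Pseudocount added before the log2 transform of FPKM/RPM.
    delta_beta_threshold : float
        Probe-level hypomethylation gate on mean Δβ (tumour − normal).
    methylation_q_threshold : float
        BH-corrected p gate for the probe-level t-test.
    paired_methylation_test : bool
        Use a paired t-test over the tumour↔normal pairs instead of the
        default unpaired Welch test.
    mirna_z_threshold : float
        z-score below which a miRNA counts as downregulated in a sample
        (-1.645, the lower 5% tail of the standard normal).
    mirna_z_scale : str
        ``"rpm"`` (default) computes z on raw RPM; ``"log2"`` on
        log2(RPM + pseudocount).
    diff_q_threshold : float
        BH gate for the paired differential miRNA screen.
    expr_min_rpm, expr_frac_at_min, expr_frac_positive : float
        Expressed-miRNA filter: >= expr_min_rpm RPM in >= expr_frac_at_min of
        samples AND > 0 RPM in >= expr_frac_positive of samples, per role.
    spearman_rho_threshold, spearman_p_threshold : float
        Anti-correlation screen gates (ρ < -0.2 and p < 0.05).
    spearman_tumour_only : bool
        Correlate across tumour samples only (default) or all shared samples.
    min_group_size : int
        Survival groups of this size or smaller merge into the nearest
        larger neighbour ("five or fewer").
    plot_max_days : float
        Kaplan-Meier plots truncate at this x-limit; tests always use full
        follow-up.
    alpha : float
        Significance level for survival tests.
    trend_weights : str
        ``"score"`` (default) weights merged groups by the mean raw score of
        their patients; ``"rank"`` uses the group rank after merging.
    """

    fence_multiplier: float = 1.5
    log2_pseudocount: float = 1.0
    delta_beta_threshold: float = -0.1
    methylation_q_threshold: float = 0.05
    paired_methylation_test: bool = False
    mirna_z_threshold: float = -1.645
    mirna_z_scale: str = "rpm"
    diff_q_threshold: float = 0.05
    expr_min_rpm: float = 1.0
    expr_frac_at_min: float = 0.10
    expr_frac_positive: float = 0.50
    spearman_rho_threshold: float = -0.2
    spearman_p_threshold: float = 0.05
    spearman_tumour_only: bool = True
    min_group_size: int = 5
    plot_max_days: float = 2000.0
    alpha: float = 0.05
    trend_weights: str = "score"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise OmicsIOError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> Config:
    with open(path, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
            raise OmicsIOError(f"malformed YAML in {path}: {exc}") from exc
    if raw is None:
        return Config()
    if not isinstance(raw, dict):
        raise OmicsIOError(f"config root must be a mapping, got {type(raw).__name__}")
    return Config.from_dict(raw)


def save_config(config: Config, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        # round_trip parsing restores written floats bit-for-bit
        return pd.read_csv(path, sep="\t", float_precision="round_trip", **kw)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise OmicsIOError(f"malformed TSV {path}: {exc}") from exc


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_roles(path: str | Path) -> pd.Series:
    df = _read_tsv(path, dtype=str)
    if list(df.columns[:2]) != ["sample", "role"]:
        raise OmicsIOError(f"role table {path} must have columns sample, role")
    if df["sample"].duplicated().any():
        raise OmicsIOError("duplicate sample in role table")
    return pd.Series(df["role"].values, index=df["sample"].values, name="role")


def _read_pairing(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, dtype=str)
    if list(df.columns[:2]) != ["tumour", "non_malignant"]:
        raise OmicsIOError(
            f"pairing table {path} must have columns tumour, non_malignant"
        )
    return dict(zip(df["tumour"], df["non_malignant"]))


def read_expression(
    path: str | Path,
    role_table_path: str | Path,
    pairing_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a feature × sample abundance matrix plus its role side table."""
    values = _read_matrix(path).astype(float)
    roles = _read_roles(role_table_path)
    pairing = _read_pairing(pairing_path) if pairing_path is not None else None
    return ExpressionMatrix(values=values, sample_role=roles, pairing=pairing)


def write_expression(
    em: ExpressionMatrix,
    path: str | Path,
    role_table_path: str | Path | None = None,
    pairing_path: str | Path | None = None,
) -> None:
    em.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="feature")
    if role_table_path is not None:
        pd.DataFrame(
            {"sample": em.sample_role.index, "role": em.sample_role.values}
        ).to_csv(role_table_path, sep="\t", index=False)
    if pairing_path is not None and em.pairing is not None:
        pd.DataFrame(
            {"tumour": list(em.pairing), "non_malignant": list(em.pairing.values())}
        ).to_csv(pairing_path, sep="\t", index=False)


def read_methylation(
    path: str | Path,
    annotation_path: str | Path,
    role_table_path: str | Path,
) -> MethylationData:
    """Read a probe × sample β matrix and its probe→gene annotation."""
    beta = _read_matrix(path).astype(float)
    ann = _read_tsv(annotation_path, dtype=str)
    needed = {"probe", "gene", "region"}
    if not needed.issubset(ann.columns):
        raise OmicsIOError(
            f"annotation {annotation_path} must have columns probe, gene, region"
        )
    if ann["probe"].duplicated().any():
        dup = ann["probe"][ann["probe"].duplicated()].iloc[0]
        raise OmicsIOError(f"probe {dup!r} annotated more than once")
    probe_gene = pd.Series(ann["gene"].values, index=ann["probe"].values, name="gene")
    probe_region = pd.Series(
        ann["region"].values, index=ann["probe"].values, name="region"
    )
    roles = _read_roles(role_table_path)
    return MethylationData(
        beta=beta, probe_gene=probe_gene, probe_region=probe_region, sample_role=roles
    )


def write_methylation(
    md: MethylationData,
    path: str | Path,
    annotation_path: str | Path | None = None,
    role_table_path: str | Path | None = None,
) -> None:
    md.beta.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="probe")
    if annotation_path is not None:
        pd.DataFrame(
            {
                "probe": md.probe_gene.index,
                "gene": md.probe_gene.values,
                "region": md.probe_region.values,
            }
        ).to_csv(annotation_path, sep="\t", index=False)
    if role_table_path is not None:
        pd.DataFrame(
            {"sample": md.sample_role.index, "role": md.sample_role.values}
        ).to_csv(role_table_path, sep="\t", index=False)


def read_cn(path: str | Path) -> CopyNumberCalls:
    df = _read_matrix(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise OmicsIOError(f"non-numeric copy-number call in {path}: {exc}") from exc
    if not (df == df.round()).all().all():
        raise OmicsIOError(f"non-integer copy-number call in {path}")
    return CopyNumberCalls(calls=df.astype(int))


def write_cn(cn: CopyNumberCalls, path: str | Path) -> None:
    cn.calls.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = _read_tsv(path)
    if "sample" not in df.columns:
        raise OmicsIOError(f"clinical table {path} must have a sample column")
    df["sample"] = df["sample"].astype(str)
    return ClinicalTable(table=df.set_index("sample")[["os_days", "event"]])


def write_clinical(ct: ClinicalTable, path: str | Path) -> None:
    ct.table.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="sample")


def read_target_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column miRNA → target-gene table into a map of sets."""
    df = _read_tsv(path, dtype=str)
    if list(df.columns[:2]) != ["mirna", "gene"]:
        raise OmicsIOError(f"target map {path} must have columns mirna, gene")
    if df.isna().any().any() or (df["mirna"].str.strip() == "").any() or (
        df["gene"].str.strip() == ""
    ).any():
        raise OmicsIOError(f"blank identifier in target map {path}")
    out: dict[str, set[str]] = {}
    for m, g in zip(df["mirna"], df["gene"]):
        out.setdefault(m, set()).add(g)
    return {m: frozenset(gs) for m, gs in out.items()}


def write_target_map(tm: dict[str, frozenset[str]], path: str | Path) -> None:
    rows = [(m, g) for m in sorted(tm) for g in sorted(tm[m])]
    pd.DataFrame(rows, columns=["mirna", "gene"]).to_csv(path, sep="\t", index=False)


def read_id_set(path: str | Path, column: str = "mirna") -> frozenset[str]:
    """Read a one-column identifier list (e.g. annotated miRNA ids)."""
    df = _read_tsv(path, dtype=str)
    if column not in df.columns:
        raise OmicsIOError(f"{path} must have a {column!r} column")
    return frozenset(df[column])


def write_id_set(ids, path: str | Path, column: str = "mirna") -> None:
    pd.DataFrame({column: sorted(ids)}).to_csv(path, sep="\t", index=False)
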