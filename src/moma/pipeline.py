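"""Stage orchestration: simulate → call → screen → score → survive.

Every stage reads and writes only TSV/YAML on disk, so each is independently
runnable and resumable; ``run_all`` executes them in order and records a
manifest (config snapshot, seed, stage timings, SHA-256 checksums of every
output) so that reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import survival as _surv
from .io import Config, OmicsIOError, read_clinical
from .model import MultiOmicsModel
from .simulate import COHORT_FILES, SimConfig, generate_cohort, write_cohort

log = logging.getLogger("moma")

__all__ = [
    "load_sim_config",
    "load_analysis_config",
    "stage_simulate",
    "stage_call",
    "stage_screen",
    "stage_score",
    "stage_survive",
    "run_all",
    "sha256_file",
]

FLOAT_FMT = "%.10g"


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from YAML (top level or under a ``simulate:`` key)."""
    with open(path, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise OmicsIOError(f"malformed YAML in {path}: {exc}") from exc
    if "simulate" in raw:
        raw = raw["simulate"] or {}
    raw.pop("analysis", None)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise OmicsIOError(f"unknown simulate keys: {sorted(unknown)}")
    return SimConfig(**raw)


def load_analysis_config(path: str | Path | None) -> Config:
    """Read analysis thresholds from YAML (top level or ``analysis:`` key)."""
    if path is None:
        return Config()
    with open(path, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise OmicsIOError(f"malformed YAML in {path}: {exc}") from exc
    if "analysis" in raw:
        return Config.from_dict(raw["analysis"] or {})
    raw.pop("simulate", None)
    return Config.from_dict(raw)


def _save(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, **kw)
    return path


def _fit(config: Config, in_dir: str | Path):
    model = MultiOmicsModel.from_directory(in_dir, config=config)
    return model, model.fit()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(sim_cfg: SimConfig, out_dir: str | Path) -> list[Path]:
    """Generate a synthetic cohort and write its TSV file set."""
    cohort = generate_cohort(sim_cfg)
    return list(write_cohort(cohort, out_dir).values())


def stage_call(config: Config, in_dir: str | Path, out_dir: str | Path) -> list[Path]:
    """Alteration calling: writes calls.tsv (long format), the probe-level
    hypomethylation screen, and the per-miRNA down-call matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _, res = _fit(config, in_dir)
    return [
        _save(res.calls_long(), out / "calls.tsv", index=False),
        _save(
            res.hypometh_probes.assign(kept=res.hypometh_probes["kept"].astype(int))
            .rename_axis("probe"),
            out / "hypometh_probes.tsv",
            index=True,
        ),
        _save(
            res.mirna_down_calls.astype(int).rename_axis("mirna"),
            out / "mirna_down_calls.tsv",
            index=True,
        ),
    ]


def stage_screen(config: Config, in_dir: str | Path, out_dir: str | Path) -> list[Path]:
    """miRNA screens: differential expression table and the miRNA×gene
    Spearman anti-correlation table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _, res = _fit(config, in_dir)
    paths = []
    if res.diff_mirna is None:
        raise OmicsIOError("screen stage needs a tumour↔normal pairing table")
    paths.append(
        _save(
            res.diff_mirna.assign(
                significant=res.diff_mirna["significant"].astype(int)
            ),
            out / "diff_mirna.tsv",
            index=True,
        )
    )
    paths.append(
        _save(
            res.corr.assign(passes=res.corr["passes"].astype(int)),
            out / "corr.tsv",
            index=False,
        )
    )
    return paths


def stage_score(in_dir: str | Path, out_dir: str | Path) -> list[Path]:
    """Build the patient × gene score table from calls.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calls_path = out / "calls.tsv"
    if not calls_path.exists():
        calls_path = Path(in_dir) / "calls.tsv"
    if not calls_path.exists():
        raise FileNotFoundError(f"missing calls table {calls_path}")
    calls = pd.read_csv(calls_path, sep="\t")

    def _wide(kind: str) -> pd.DataFrame:
        sub = calls[calls["call_type"] == kind]
        return sub.pivot(index="gene", columns="sample", values="flag").astype(bool)

    scores = _surv.build_scores(
        _wide("overexpressed"),
        _wide("mirna_majority_down"),
        _wide("cn_increase"),
        _wide("hypomethylated"),
    )
    return [_save(scores.rename_axis("sample"), out / "scores.tsv", index=True)]


def stage_survive(
    config: Config, in_dir: str | Path, out_dir: str | Path, plots: bool = False
) -> list[Path]:
    """Survival stage: per-gene score stratifications, the panel-wide
    overexpression-count stratification, KM curves and optional SVG plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores_path = out / "scores.tsv"
    if not scores_path.exists():
        raise FileNotFoundError(f"missing score table {scores_path}")
    scores = pd.read_csv(scores_path, sep="\t", index_col="sample")
    scores.index = scores.index.astype(str)
    clinical_path = Path(in_dir) / COHORT_FILES["clinical"]
    if not clinical_path.exists():
        raise FileNotFoundError(f"missing clinical table {clinical_path}")
    clinical = read_clinical(clinical_path).table.loc[scores.index]
    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    over = (
        calls[calls["call_type"] == "overexpressed"]
        .pivot(index="gene", columns="sample", values="flag")
        .astype(bool)[scores.index]
    )

    tests, strata = [], {}
    for g in scores.columns:
        res, labels = _surv.stratify_by_score(
            scores[g], clinical, min_size=config.min_group_size
        )
        tests.append((f"score_{g}", res))
        strata[f"score_{g}"] = labels
    oe_res, oe_labels = _surv.stratify_by_overexpression_count(
        over, clinical, min_size=config.min_group_size
    )
    tests.append(("overexpression_count", oe_res))
    strata["overexpression_count"] = oe_labels

    rows = [
        {
            "test_name": name,
            "test": r.test,
            "groups": ";".join(str(l) for l in r.group_labels),
            "sizes": ";".join(str(n) for n in r.group_sizes),
            "chi2": r.statistic,
            "df": r.df,
            "p": r.p,
        }
        for name, r in tests
        if r is not None
    ]
    paths = [
        _save(
            pd.DataFrame(
                rows,
                columns=["test_name", "test", "groups", "sizes", "chi2", "df", "p"],
            ),
            out / "tests.tsv",
            index=False,
        )
    ]

    km_rows = []
    for name, labels in strata.items():
        for lab in sorted(labels.unique(), key=str):
            sel = labels == lab
            curve = _surv.km_estimate(
                clinical.loc[sel, "os_days"], clinical.loc[sel, "event"]
            )
            for t, n, d, s in zip(
                curve.event_times, curve.at_risk, curve.n_events, curve.survival
            ):
                km_rows.append((name, lab, t, int(n), int(d), s))
    paths.append(
        _save(
            pd.DataFrame(
                km_rows,
                columns=[
                    "stratification",
                    "group",
                    "time",
                    "at_risk",
                    "events",
                    "survival",
                ],
            ),
            out / "km_curves.tsv",
            index=False,
        )
    )

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for name, labels in strata.items():
            curves = {}
            for lab in sorted(labels.unique(), key=str):
                sel = labels == lab
                curves[str(lab)] = _surv.km_estimate(
                    clinical.loc[sel, "os_days"], clinical.loc[sel, "event"]
                )
            ax = _surv.plot_km(curves, max_days=config.plot_max_days)
            ax.set_title(name)
            fig_path = out / f"km_{name}.svg"
            ax.figure.savefig(fig_path)
            plt.close(ax.figure)
            paths.append(fig_path)
    return paths


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------


def run_all(
    out_dir: str | Path,
    sim_cfg: SimConfig | None = None,
    in_dir: str | Path | None = None,
    config: Config | None = None,
    plots: bool = False,
) -> dict:
    """Execute the full pipeline and return the run manifest.

    Either ``sim_cfg`` (generate inputs under ``out_dir/cohort``) or
    ``in_dir`` (existing cohort directory) must be given.  Any stage failure
    aborts with the stage name attached.  The manifest records the config
    snapshot, seed, stage timings and a SHA-256 checksum of every input and
    output file; deterministic stages reproduce identical checksums on
    rerun.
    """
    if (sim_cfg is None) == (in_dir is None):
        raise ValueError("give exactly one of sim_cfg or in_dir")
    config = config or Config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_dir = out / "results"
    manifest: dict = {
        "version": __version__,
        "seed": sim_cfg.seed if sim_cfg else None,
        "config": config.to_dict(),
        "sim_config": (
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(sim_cfg).items()
            }
            if sim_cfg
            else None
        ),
        "stages": [],
    }

    def _run(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            outputs = fn(*args, **kw)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {
                "name": name,
                "seconds": round(time.perf_counter() - t0, 4),
                "outputs": {Path(p).name: sha256_file(p) for p in outputs},
            }
        )
        log.info("stage %s: %d output files", name, len(outputs))
        return outputs

    if sim_cfg is not None:
        in_dir = out / "cohort"
        _run("simulate", stage_simulate, sim_cfg, in_dir)
    in_dir = Path(in_dir)
    manifest["input_checksums"] = {
        p.name: sha256_file(p) for p in sorted(in_dir.glob("*.tsv"))
    }
    _run("call", stage_call, config, in_dir, results_dir)
    _run("screen", stage_screen, config, in_dir, results_dir)
    _run("score", stage_score, in_dir, results_dir)
    _run("survive", stage_survive, config, in_dir, results_dir, plots=plots)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
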