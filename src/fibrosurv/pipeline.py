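"""End-to-end reproducible pipeline runs and report generation.

One YAML/JSON config drives the full chain: synthetic slides per patient ->
per-patient CVF quantification -> cohort merge -> cutpoint scan -> survival
models -> Markdown/CSV/JSON reports plus Kaplan–Meier figures, with a
manifest listing every output and its content hash.  Every stochastic stage
takes its seed from the config; two runs with the same config are
numerically identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import cvfquant
from .cutpoint import scan_cutpoints
from .cox import two_predictor_ladder
from .imputation import impute_pmm_bootstrap
from .survstats import compare_groups, km_estimate, logrank_test, proportion_percent
from .synthcohort import CohortSpec, endpoint_columns, simulate_cohort
from .synthslide import default_palette, generate_fragment, sample_training_pixels

logger = logging.getLogger("fibrosurv")

__all__ = ["RunConfig", "run_pipeline", "event_rate_table"]

#: the eight canonical imputation variables
IMPUTATION_VARIABLES = [
    "cvf_percent",
    "age",
    "bmi",
    "lvef",
    "log_ntprobnp",
    "nyha",
    "log_creatinine",
    "diabetes",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Seeds are mandatory for every stochastic stage; loading a config without
    them fails validation rather than defaulting silently.
    """

    out_dir: str
    n_patients: int = 50
    fragments_per_patient: int = 2
    fragment_area_mm2: float = 1.0
    stain: str = "trichrome"
    slide_seed: int | None = None
    cohort_seed: int | None = None
    imputation_seed: int | None = None
    train_pixels_per_class: int = 2000
    opening_radius_px: int = cvfquant.DEFAULT_OPENING_RADIUS_PX
    roi_threshold: float = cvfquant.DEFAULT_ROI_THRESHOLD
    min_fragment_area_mm2: float = cvfquant.DEFAULT_MIN_FRAGMENT_AREA_MM2
    endpoint: str = "composite"
    imputation_m: int = 10
    missing_rates: dict = field(default_factory=dict)
    cutpoint_lo: int = 5
    cutpoint_hi: int = 95
    cohort_overrides: dict = field(default_factory=dict)
    write_slides: bool = False

    def validate(self) -> None:
        for name in ("slide_seed", "cohort_seed", "imputation_seed"):
            if getattr(self, name) is None:
                raise ValueError(f"config missing required seed {name!r}")
        if self.n_patients <= 0 or self.fragments_per_patient <= 0:
            raise ValueError("n_patients and fragments_per_patient must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def event_rate_table(
    event_counts: dict[str, int],
    group_sizes: dict[str, int],
    logrank_p: float | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-group event percentages at fixed decimals, with an optional p.

    The percentage arithmetic is exact half-up rounding of 100*count/size,
    matching how clinical tables print rates.
    """
    rows = []
    for grp, count in event_counts.items():
        size = group_sizes[grp]
        if size <= 0:
            raise ValueError(f"group {grp!r} has size 0")
        if count > size:
            raise ValueError(f"count exceeds size for group {grp!r}")
        rows.append(
            {
                "group": grp,
                "events": count,
                "n": size,
                "percent": proportion_percent(count, size, decimals),
                "logrank_p": logrank_p,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _quantify_patients(config: RunConfig) -> pd.DataFrame:
    """Generate fragments per patient, quantify them, pool per patient."""
    rng = np.random.default_rng(config.slide_seed)
    palette = default_palette(config.stain)
    # planted per-patient CVF drawn from the cohort's fibrosis distribution
    spec = CohortSpec(n=config.n_patients, seed=config.cohort_seed, **config.cohort_overrides)
    from scipy.stats import truncnorm

    clo, chi = spec.cvf_bounds
    ca = (clo - spec.cvf_mean) / spec.cvf_sd
    cb = (chi - spec.cvf_mean) / spec.cvf_sd
    planted = truncnorm.rvs(
        ca, cb, loc=spec.cvf_mean, scale=spec.cvf_sd, size=config.n_patients, random_state=rng
    )

    train_slide = generate_fragment(
        area_mm2=config.fragment_area_mm2,
        target_cvf_percent=35.0,
        palette=palette,
        seed=int(rng.integers(2**31)),
        fragment_id="training",
    )
    training = sample_training_pixels(
        train_slide, n_per_class=config.train_pixels_per_class, seed=int(rng.integers(2**31))
    )
    clf = cvfquant.train_classifier(training)

    rows = []
    for i in range(config.n_patients):
        frags = []
        for j in range(config.fragments_per_patient):
            slide = generate_fragment(
                area_mm2=config.fragment_area_mm2,
                target_cvf_percent=float(planted[i]),
                palette=palette,
                seed=int(rng.integers(2**31)),
                fragment_id=f"P{i:05d}-F{j}",
            )
            frags.append(
                cvfquant.quantify_slide(
                    slide,
                    clf,
                    roi_threshold=config.roi_threshold,
                    opening_radius_px=config.opening_radius_px,
                    min_fragment_area_mm2=config.min_fragment_area_mm2,
                )
            )
        # QC thresholds follow the configured fragment size so reduced-scale
        # runs are not wholly excluded by the clinical-scale defaults
        retained, excluded = cvfquant.quality_filter(
            frags,
            min_tissue_mm2=min(
                cvfquant.DEFAULT_MIN_FRAGMENT_TISSUE_MM2, 0.8 * config.fragment_area_mm2
            ),
        )
        patient = cvfquant.aggregate_patient(
            f"P{i:05d}",
            retained,
            excluded,
            min_total_tissue_mm2=min(
                cvfquant.DEFAULT_MIN_PATIENT_TISSUE_MM2,
                0.8 * config.fragment_area_mm2 * config.fragments_per_patient,
            ),
        )
        rows.append(
            {
                "patient_id": patient.patient_id,
                "planted_cvf_percent": float(planted[i]),
                "measured_cvf_percent": patient.cvf_percent,
                "total_fibrosis_mm2": patient.total_fibrosis_mm2,
                "total_muscle_mm2": patient.total_muscle_mm2,
                "n_fragments_retained": len(patient.fragments),
                "n_fragments_excluded": len(patient.qc_excluded_fragments),
                "usable": patient.usable,
            }
        )
    return pd.DataFrame(rows)


def _km_figure(cohort: pd.DataFrame, endpoint: str, cutpoint: float, path: Path) -> None:
    dur_col, ev_col = endpoint_columns(endpoint)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, mask in (
        (f"CVF < {cutpoint:g}%", cohort["cvf_percent"] < cutpoint),
        (f"CVF >= {cutpoint:g}%", cohort["cvf_percent"] >= cutpoint),
    ):
        sub = cohort[mask]
        if len(sub) == 0:
            continue
        curve = km_estimate(sub[dur_col], sub[ev_col], group_label=label)
        ts = np.concatenate([[0.0], np.repeat(curve.event_times, 2), [cohort[dur_col].max()]])
        ss = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1], [curve.survival[-1] if len(curve.survival) else 1.0]])
        ax.plot(ts, ss[: len(ts)], drawstyle="steps-post", label=label)
    ax.set_xlabel("years")
    ax.set_ylabel("event-free survival")
    ax.set_ylim(0, 1.05)
    ax.legend()
    ax.set_title(f"Kaplan–Meier, {endpoint} endpoint")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure raises with the stage name; outputs written up to that
    point are left in place for inspection.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage = "setup"
    try:
        stage = "quantify"
        logger.info("stage %s: %d patients x %d fragments", stage, config.n_patients, config.fragments_per_patient)
        cvf_table = _quantify_patients(config)
        p = out / "patient_cvf.csv"
        cvf_table.to_csv(p, index=False)
        outputs.append(p)
        logger.info("stage %s: %d/%d patients usable", stage, int(cvf_table["usable"].sum()), len(cvf_table))

        stage = "cohort"
        spec = CohortSpec(
            n=config.n_patients,
            seed=config.cohort_seed,
            cvf_values=cvf_table["planted_cvf_percent"].to_numpy(),
            missing_rates=config.missing_rates,
            **config.cohort_overrides,
        )
        cohort = simulate_cohort(spec)
        cohort = cohort.merge(
            cvf_table[["patient_id", "measured_cvf_percent"]], on="patient_id"
        )
        # analysis uses the measured CVF, as a real study would
        cohort["cvf_percent"] = cohort["measured_cvf_percent"]
        p = out / "cohort.csv"
        cohort.to_csv(p, index=False)
        outputs.append(p)

        stage = "cutpoint_scan"
        scan = scan_cutpoints(
            cohort, endpoint=config.endpoint, lo=config.cutpoint_lo, hi=config.cutpoint_hi
        )
        p = out / "cutpoint_scan.json"
        p.write_text(
            json.dumps(
                {
                    "optimal_cutpoint": scan.optimal_cutpoint,
                    "endpoint": scan.endpoint,
                    "rows": scan.to_frame().replace({np.nan: None}).to_dict("records"),
                },
                indent=1,
            )
        )
        outputs.append(p)
        cut = float(scan.optimal_cutpoint)
        logger.info("stage %s: optimal cutpoint %g%%", stage, cut)

        stage = "group_comparison"
        group = (cohort["cvf_percent"] >= cut).map({True: "high_cvf", False: "low_cvf"})
        table1 = []
        for var, kind in (
            ("age", "mean"),
            ("bmi", "mean"),
            ("lvef", "mean"),
            ("ntprobnp", "median"),
            ("creatinine", "median"),
            ("diabetes", "categorical"),
            ("nyha", "categorical"),
        ):
            cmp = compare_groups(cohort[var].to_numpy(), group.to_numpy(), kind)
            table1.append({"variable": var, "kind": kind, "p_value": cmp["p_value"], "groups": cmp["groups"]})
        p = out / "table1_group_comparison.json"
        p.write_text(json.dumps(table1, indent=1, default=str))
        outputs.append(p)

        stage = "models"
        if any(cohort[v].isna().any() for v in IMPUTATION_VARIABLES):
            imp = impute_pmm_bootstrap(
                cohort,
                IMPUTATION_VARIABLES,
                m=config.imputation_m,
                seed=config.imputation_seed,
            )
            datasets = imp.datasets
        else:
            datasets = cohort
        predictors = {
            "age_per10": ["age"],
            "bmi": ["bmi"],
            "lvef": ["lvef"],
            "log_ntprobnp": ["log_ntprobnp"],
            "log_creatinine": ["log_creatinine"],
            "diabetes": ["diabetes"],
        }
        ladder = two_predictor_ladder(
            datasets,
            *endpoint_columns(config.endpoint),
            predictors=predictors,
            adjust_name="cvf_percent",
        )
        p = out / "model_ladder.csv"
        ladder.to_csv(p, index=False)
        outputs.append(p)
        md = out / "model_ladder.md"
        md.write_text(_ladder_markdown(ladder))
        outputs.append(md)

        stage = "event_rates"
        rates = {}
        for endpoint in ("composite", "death"):
            dur_col, ev_col = endpoint_columns(endpoint)
            high = cohort["cvf_percent"] >= cut
            counts = {
                "high_cvf": int(cohort.loc[high, ev_col].sum()),
                "low_cvf": int(cohort.loc[~high, ev_col].sum()),
            }
            sizes = {"high_cvf": int(high.sum()), "low_cvf": int((~high).sum())}
            lr = logrank_test(cohort[dur_col], cohort[ev_col], high.astype(int))
            rates[endpoint] = event_rate_table(counts, sizes, logrank_p=lr.p_value).to_dict(
                "records"
            )
        p = out / "event_rates.json"
        p.write_text(json.dumps(rates, indent=1))
        outputs.append(p)

        stage = "km_figures"
        for endpoint in ("composite", "death"):
            p = out / f"km_{endpoint}.png"
            _km_figure(cohort, endpoint, cut, p)
            outputs.append(p)

        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(config),
            "outputs": {q.name: _sha256(q) for q in outputs},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _ladder_markdown(ladder: pd.DataFrame) -> str:
    lines = [
        "| Predictor | HR (95% CI) | p | AIC | HR (95% CI) adj. CVF | p adj. | AIC adj. |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, r in ladder.iterrows():
        if r["status"] != "ok":
            lines.append(f"| {r['predictor']} | {r['status']} | | | | | |")
            continue

        def _fmt(prefix: str) -> tuple[str, str, str]:
            lo, hi = r[f"{prefix}_ci95"]
            return (
                f"{r[f'{prefix}_hr']:.2f} ({lo:.2f}–{hi:.2f})",
                f"{r[f'{prefix}_p']:.3g}",
                f"{r[f'{prefix}_aic']:.1f}",
            )

        s = _fmt("single")
        a = _fmt("adjusted")
        lines.append(
            f"| {r['predictor']} | {s[0]} | {s[1]} | {s[2]} | {a[0]} | {a[1]} | {a[2]} |"
        )
    return "\n".join(lines) + "\n"
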