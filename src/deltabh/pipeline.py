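"""End-to-end orchestration: simulate -> curate -> featurize -> train ->
evaluate -> explain -> thermochemistry, with versioned, hash-stamped outputs.

Every stage writes its artifact under a run directory; the resolved
configuration, its hash and the library versions are recorded so a run can
be reproduced exactly.  Tree and GP metrics are bit-stable for a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curation import curate_dataset
from .features import assemble, correlation_filter, importance_subset, targets
from .models import (
    SplitSpec,
    corrected_bh,
    evaluate,
    explain,
    split,
    train,
)
from .sqm import save_records
from .synthetic import GeneratorConfig, gen_dataset
from .thermo import delta_g_activation, thermo_input_from_species


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run (all thresholds explicit)."""

    n_reactions: int = 500
    seed: int = 0
    noise_sd: float = 2.0
    failure_fractions: dict = field(default_factory=dict)
    model_kinds: tuple[str, ...] = ("xgb", "gp")
    correlation_threshold: float = 0.9
    split_fractions: tuple[float, float, float] = (0.85, 0.05, 0.10)
    reduced_set_size: int = 49
    hpo_budget: int = 6
    gp_max_train: int | None = 1000
    temperatures: tuple[float, ...] = (300.0, 500.0, 1000.0)
    freq_scale_low: float = 1.0     # low-level harmonic-frequency scaling
    freq_scale_ref: float = 0.9914  # reference-level recommended scaling
    families: tuple[str, ...] = ("rdkit", "topol", "bonds", "pm7")
    out_dir: str = "runs"

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["model_kinds"] = list(self.model_kinds)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) config file into a RunConfig."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("model_kinds", "split_fractions", "temperatures", "families"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage; returns the run directory containing all artifacts."""
    cfg_hash = config.hash()
    base = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    run_dir = base / f"run_{time.strftime('%Y%m%d-%H%M%S')}_{cfg_hash}"
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(
        json.dumps(
            {
                "config": config.resolved(),
                "config_hash": cfg_hash,
                "deltabh_version": __version__,
            },
            indent=2,
        )
    )

    # --- simulate ---
    gen_cfg = GeneratorConfig(
        n_reactions=config.n_reactions,
        seed=config.seed,
        noise_sd=config.noise_sd,
        failure_fractions=dict(config.failure_fractions),
    )
    records, raws, truth = gen_dataset(gen_cfg)
    save_records(run_dir / "records.json", records)

    # --- curate ---
    kept_raw, reports, counts = curate_dataset(raws)
    kept_ids = {rep.record_id for rep in reports if rep.kept}
    kept = [r for r in records if r.record_id in kept_ids]
    curation_rows = [
        {
            "record_id": rep.record_id,
            "kept": rep.kept,
            "reason": rep.reason.value,
            "direction": "/".join(rep.direction_assignment)
            if rep.direction_assignment
            else "",
        }
        for rep in reports
    ]
    pd.DataFrame(curation_rows).to_csv(run_dir / "curation.tsv", sep="\t", index=False)
    (run_dir / "curation_summary.json").write_text(json.dumps(counts, indent=2))

    # --- featurize ---
    fm = assemble(kept, families=config.families)
    tgt = targets(kept)
    tr, va, te = split(len(kept), SplitSpec(config.split_fractions, config.seed))
    fm = correlation_filter(fm, config.correlation_threshold, reference_rows=tr)
    fm.to_csv(run_dir / "features.csv")

    # --- train / evaluate / explain ---
    y = tgt["delta"].to_numpy()
    metrics: dict = {
        "config_hash": cfg_hash,
        "n_generated": config.n_reactions,
        "curation": counts,
        "n_features": len(fm.names),
        "split_sizes": [len(tr), len(va), len(te)],
        "baseline_mae_uncorrected": float(np.abs(y[te]).mean()),
        "models": {},
    }
    xgb_model = None
    for kind in config.model_kinds:
        if kind == "multitask_nn":
            y_fit = tgt[["delta", "de_r"]].to_numpy()[tr]
        else:
            y_fit = y[tr]
        model = train(
            kind,
            fm.df.iloc[tr],
            y_fit,
            hpo_budget=config.hpo_budget,
            seed=config.seed,
            gp_max_train=config.gp_max_train,
        )
        report = evaluate(model, fm.df.iloc[te], y[te])
        bh_corr = corrected_bh(model, fm.df.iloc[te], tgt["bh_pm7"].to_numpy()[te])
        mae_corr = float(np.abs(bh_corr - tgt["bh_dft"].to_numpy()[te]).mean())
        metrics["models"][kind] = {
            "test_mae": report.mae,
            "corrected_bh_mae": mae_corr,
            "histogram_counts": report.histogram_counts.tolist(),
            "histogram_edges": report.histogram_edges.tolist(),
        }
        from .models import save_model
        from .plots import error_histogram, parity_plot

        save_model(model, run_dir / f"model_{kind}.pkl")
        parity_plot(
            tgt["bh_dft"].to_numpy()[te], bh_corr, run_dir / f"parity_{kind}.png"
        )
        error_histogram(report.errors, run_dir / f"errors_{kind}.png")
        if kind == "xgb":
            xgb_model = model

    if xgb_model is not None:
        reduced = importance_subset(xgb_model, fm, k=min(config.reduced_set_size, len(fm.names)))
        (run_dir / "reduced_set.json").write_text(
            json.dumps({"selected": reduced.selected, "importances": reduced.importances}, indent=2)
        )
        attribution = explain(xgb_model, fm.df.iloc[te])
        metrics["top_features"] = attribution.ranking[:20]
        metrics["custom_in_top20"] = sum(
            1 for name in attribution.ranking[:20] if not name.startswith("rdkit.")
        )

    # --- thermochemistry: activation Gibbs energies per kept record ---
    thermo_rows = []
    dg_err: dict[float, list[float]] = {T: [] for T in config.temperatures}
    delta_pred = None
    if xgb_model is not None:
        delta_pred = xgb_model.predict(fm.df)
    for i, rec in enumerate(kept):
        inp_r = thermo_input_from_species(
            rec.geom_reactant, rec.reactant.frequencies, rec.reactant.energy,
            scale_factor=config.freq_scale_low,
        )
        inp_ts = thermo_input_from_species(
            rec.geom_ts, rec.ts.frequencies, rec.ts.energy,
            scale_factor=config.freq_scale_low,
        )
        # reference level: its own frequency scaling and the true correction
        # on the TS electronic energy
        ref_r = thermo_input_from_species(
            rec.geom_reactant, rec.reactant.frequencies, rec.reactant.energy,
            scale_factor=config.freq_scale_ref,
        )
        ref_ts = thermo_input_from_species(
            rec.geom_ts, rec.ts.frequencies, rec.ts.energy + rec.target,
            scale_factor=config.freq_scale_ref,
        )
        row = {"record_id": rec.record_id}
        for T in config.temperatures:
            dg_low = delta_g_activation(inp_r, inp_ts, T)
            dg_ref = delta_g_activation(ref_r, ref_ts, T)
            row[f"dg_low_{int(T)}K"] = dg_low
            row[f"dg_ref_{int(T)}K"] = dg_ref
            if delta_pred is not None:
                dg_ml = dg_low + float(delta_pred[i])
                row[f"dg_ml_{int(T)}K"] = dg_ml
                dg_err[T].append(abs(dg_ml - dg_ref))
        thermo_rows.append(row)
    pd.DataFrame(thermo_rows).to_csv(run_dir / "thermo.tsv", sep="\t", index=False)
    if delta_pred is not None:
        metrics["dg_activation_mae"] = {
            str(int(T)): float(np.mean(v)) for T, v in dg_err.items() if v
        }

    (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return run_dir
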