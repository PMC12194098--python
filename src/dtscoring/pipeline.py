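"""End-to-end study pipelines.

Three entry points mirror the analysis arc of a rater-controlled
divergent-thinking study: model selection and rater parameters (aim 1),
reliability and the originality-fluency confound across scoring schemes
(aim 2), and planned-missingness robustness (aim 3).  Every stage derives
its randomness from the global seed, and each run writes a manifest with
the configuration, seed, and any warnings so outputs are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import infit_outfit, jcc, parallel_analysis
from .irt import ModelSpec, RaterIRT, compare_models, tif
from .mfrm import fit_mfrm
from .missingness import MissingDesign, run_missingness_experiment
from .reliability import reliability_report
from .scoring import score_matrix
from .sem import scheme_correlation_table
from .synthetic import GeneratorConfig, SyntheticStudy, generate_study

ALL_FAMILIES = ("rsm", "grsm", "pcm", "gpcm", "cgrsm", "cgrm", "grm")
REPORT_SCHEMES = ("average", "irt_individual", "max1", "max2", "max3", "max4",
                  "max5", "snapshot", "irt_snapshot")


@dataclass
class PipelineConfig:
    """Configuration for the aim pipelines (YAML/JSON loadable)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    families: tuple = ALL_FAMILIES
    n_quad: int = 101
    quad_range: tuple = (-6.0, 6.0)
    bootstrap_b: int = 1000
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = GeneratorConfig(**raw.pop("generator", {}))
        cfg = cls(generator=gen, **raw)
        cfg.generator = dataclasses.replace(gen, seed=raw.get("seed", gen.seed))
        return cfg


def _manifest(outdir: Path, config: PipelineConfig, stage: str, notes) -> None:
    payload = {
        "stage": stage,
        "seed": config.seed,
        "version": __version__,
        "generator": {k: (list(v) if isinstance(v, tuple) and not hasattr(v[0], "rater_id")
                          else v)
                      for k, v in dataclasses.asdict(config.generator).items()
                      if k not in ("individual_raters", "snapshot_raters")},
        "warnings": [str(n) for n in notes],
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=2,
                                                              default=str))


def _study(config: PipelineConfig) -> SyntheticStudy:
    gen = dataclasses.replace(config.generator, seed=config.seed)
    return generate_study(gen)


def _rater_table(model: RaterIRT, wide) -> pd.DataFrame:
    fits = infit_outfit(model, wide)
    rows = []
    for p in model.rater_params_:
        row = {"rater_id": p.rater_id, "a": p.a}
        thr = p.d if p.d is not None else p.b
        for i, v in enumerate(thr, start=1):
            row[f"d{i}"] = v
        row["outfit"] = fits.loc[p.rater_id, "outfit"]
        row["infit"] = fits.loc[p.rater_id, "infit"]
        rows.append(row)
    return pd.DataFrame(rows)


def run_aim1(config: PipelineConfig, outdir) -> dict:
    """Model comparison, rater parameters, dimensionality, and curves."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = _study(config)
    results = {}
    with warnings.catch_warnings(record=True) as notes:
        warnings.simplefilter("always")
        for label, table in (("individual", study.individual_table),
                             ("snapshot", study.snapshot_table)):
            from .rating_data import to_wide
            wide = to_wide(table)
            specs = [ModelSpec(f, table.K, config.n_quad, config.quad_range)
                     for f in config.families]
            comparison = compare_models(specs, wide)
            fits = comparison.attrs.get("fits", {})
            mf = fit_mfrm(table, n_quad=config.n_quad, quad_range=config.quad_range)
            mf_row = pd.DataFrame([{"family": "mfrm", "loglik": mf.loglik_,
                                    "n_params": mf.n_params_, "aic": mf.aic_,
                                    "bic": mf.bic_, "converged": mf.converged_,
                                    "error": "", "aic_best": False, "bic_best": False}])
            comparison = pd.concat([comparison, mf_row], ignore_index=True)
            comparison = comparison.sort_values("aic").reset_index(drop=True)
            comparison[["aic_best", "bic_best"]] = False
            comparison.loc[comparison["aic"].idxmin(), "aic_best"] = True
            comparison.loc[comparison["bic"].idxmin(), "bic_best"] = True
            comparison.to_csv(outdir / f"model_comparison_{label}.csv", index=False)

            best = fits.get("grm")
            if best is None:
                best = RaterIRT(family="grm", K=table.K, n_quad=config.n_quad,
                                quad_range=config.quad_range).fit(wide)
            _rater_table(best, wide).to_csv(outdir / f"rater_params_{label}.csv",
                                            index=False)
            grid = np.arange(-4.0, 4.0001, 0.01)
            pd.DataFrame({"theta": grid, "tif": tif(best, grid)}).to_csv(
                outdir / f"tif_{label}.csv", index=False)
            curves = []
            for p in best.rater_params_:
                c = jcc(best, p.rater_id, grid)
                c.insert(0, "rater_id", p.rater_id)
                c["sorted"] = c.attrs["sorted"]
                curves.append(c)
            pd.concat(curves, ignore_index=True).to_csv(outdir / f"jcc_{label}.csv",
                                                        index=False)
            report = parallel_analysis(wide, seed=config.seed)
            (outdir / f"dimensionality_{label}.json").write_text(json.dumps({
                "eigenvalues": list(report.eigenvalues),
                "reference": list(report.reference),
                "n_retained": report.n_retained,
                "ratio_1_2": report.ratio_1_2}, indent=2))
            results[label] = {"comparison": comparison, "model": best}
        _manifest(outdir, config, "aim1", notes)
    return results


def _all_scores(config: PipelineConfig, study: SyntheticStudy):
    from .rating_data import to_wide
    wide_ind = to_wide(study.individual_table)
    wide_snap = to_wide(study.snapshot_table)
    kw = dict(K=config.generator.K, n_quad=config.n_quad, quad_range=config.quad_range)
    m_ind = RaterIRT(family="grm", **kw).fit(wide_ind)
    m_snap = RaterIRT(family="grm", **kw).fit(wide_snap)
    scores = score_matrix(study.individual_table, study.snapshot_table,
                          m_ind.eap(wide_ind), m_snap.eap(wide_snap))
    return scores


def run_aim2(config: PipelineConfig, outdir) -> dict:
    """Reliability coefficients and latent scheme/fluency correlations."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = _study(config)
    with warnings.catch_warnings(record=True) as notes:
        warnings.simplefilter("always")
        scores = _all_scores(config, study)
        task_cols = lambda f: f.drop(columns=["composite"])
        rel_rows = []
        for scheme in ("fluency",) + REPORT_SCHEMES:
            rep = reliability_report(task_cols(scores[scheme]), B=config.bootstrap_b,
                                     seed=config.seed)
            rel_rows.append({
                "scheme": scheme, "alpha": rep.alpha, "omega": rep.omega,
                "hancock_h": rep.hancock_h,
                **{f"{k}_low": v[0] for k, v in rep.ci.items()},
                **{f"{k}_high": v[1] for k, v in rep.ci.items()}})
        rel = pd.DataFrame(rel_rows)
        rel.to_csv(outdir / "reliability.csv", index=False)
        latent = scheme_correlation_table(
            {s: task_cols(scores[s]) for s in REPORT_SCHEMES},
            fluency=task_cols(scores["fluency"]))
        latent.to_csv(outdir / "latent_correlations.csv")
        _manifest(outdir, config, "aim2", notes)
    return {"reliability": rel, "latent": latent, "scores": scores}


def run_aim3(config: PipelineConfig, outdir) -> dict:
    """Planned-missingness robustness: 2-of-3 and 2-of-5 designs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = _study(config)
    with warnings.catch_warnings(record=True) as notes:
        warnings.simplefilter("always")
        report = run_missingness_experiment(
            study.individual_table, study.snapshot_table,
            MissingDesign(len(study.individual_table.raters), 2, config.seed),
            MissingDesign(len(study.snapshot_table.raters), 2, config.seed + 1),
            seed=config.seed)
        report.correlations.to_csv(outdir / "full_vs_reduced.csv")
        report.reliability.to_csv(outdir / "reliability_missingness.csv")
        (outdir / "missing_fractions.json").write_text(
            json.dumps(report.missing_fractions, indent=2))
        _manifest(outdir, config, "aim3", notes)
    return {"report": report}
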