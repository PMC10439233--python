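"""End-to-end orchestration of the whistle-repertoire analysis.

Stage order mirrors the analysis: synthesize (or load) contours ->
acoustic features + ecotype comparison -> DTW dissimilarity matrix ->
ordination / k-medoids -> MRPP + dispersion -> ART categorization ->
random-forest classification -> repertoire diversity.  Every stage writes
its artifact under the output directory and contributes a block to
``summary.json``; a stage can be skipped when its artifact already exists.

A single top-level seed expands into per-stage seeds by
``(seed * 1009 + stage_index) % 2**31`` so any stage can be rerun in
isolation with the same stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import art, contours, diversity, dtw, ordination, rf, simulate

log = logging.getLogger("stenella")

STAGES = ("simulate", "features", "dtw", "ordinate", "mrpp", "categorize", "classify", "diversity")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, serializable to/from YAML."""

    outdir: str = "results/pipeline"
    seed: int = 0
    input_contours: str | None = None  # long CSV; None -> synthesize
    n_per: int = 100
    n_groups: int = 3
    dtw_weights: dict = field(
        default_factory=lambda: {
            "time_weight": 10.0,
            "f0_weight": 3.513,
            "f0_change_weight": 2.413,
            "vibrato_weight": 1.973,
        }
    )
    dtw_resample_ms: float = 10.0
    nmmds_restarts: int = 4
    group_test_permutations: int = 1000
    vigilance: float = 96.0
    art_resample_ms: float = 10.0
    art_max_iterations: int = 50
    n_trees: int = 300
    train_frac: float = 0.67
    cv_folds: int = 10
    cv_repeats: int = 3
    mtry_grid: list | None = None
    diversity_bootstrap: int = 200
    diversity_ci: float = 0.84
    specificity_permutations: int = 1000

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + STAGES.index(stage)) % 2**31

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _round(obj, nd=6):
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round(obj.tolist(), nd)
    return obj


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all) and return the summary dict.

    Skipped stages must have left their artifact in ``cfg.outdir`` from a
    previous run; a missing upstream artifact raises an error naming it.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary_path = out / "summary.json"
    summary = json.loads(summary_path.read_text()) if summary_path.exists() else {}
    summary["config"] = _round(dataclasses.asdict(cfg))

    def need(path: Path, artifact: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(f"missing upstream artifact: {artifact} ({path})")
        return path

    def timed(stage, fn):
        t0 = time.time()
        block = fn()
        log.info("stage=%s seed=%d wall=%.2fs", stage, cfg.stage_seed(stage), time.time() - t0)
        summary[stage] = _round(block)
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))

    # --- simulate -----------------------------------------------------------
    if "simulate" in stages:
        def _simulate():
            if cfg.input_contours:
                cs = contours.read_contours(cfg.input_contours)
                truth = pd.DataFrame(
                    {
                        "whistle_id": [c.whistle_id for c in cs],
                        "ecotype": [c.meta.get("ecotype", "unknown") for c in cs],
                        "group_id": [c.meta.get("group_id", "g0") for c in cs],
                        "shape_class": [c.meta.get("shape_class", "") for c in cs],
                    }
                )
            else:
                cs, truth = simulate.make_two_ecotype_dataset(
                    cfg.n_per, cfg.stage_seed("simulate"), n_groups=cfg.n_groups
                )
            contours.write_contours(cs, out / "contours.csv")
            truth.to_csv(out / "truth.csv", index=False)
            return {"n_whistles": len(cs), "per_ecotype": truth["ecotype"].value_counts().to_dict()}

        timed("simulate", _simulate)

    def load_contours():
        return contours.read_contours(need(out / "contours.csv", "simulate.contours"))

    def load_truth():
        return pd.read_csv(need(out / "truth.csv", "simulate.truth"))

    # --- features -----------------------------------------------------------
    if "features" in stages:
        def _features():
            cs = load_contours()
            feats = contours.features_table(cs)
            feats.to_csv(out / "features.csv", index=False)
            mw = contours.mann_whitney_by_ecotype(feats)
            mw.to_csv(out / "mann_whitney.csv")
            return {
                "n": len(feats),
                "mann_whitney": {
                    p: {"W": r["W"], "p_adjusted": r["p_adjusted"], "significant": bool(r["significant"])}
                    for p, r in mw.iterrows()
                },
            }

        timed("features", _features)

    # --- dtw ----------------------------------------------------------------
    if "dtw" in stages:
        def _dtw():
            cs = load_contours()
            w = dtw.DtwWeights(**cfg.dtw_weights)
            D = dtw.build_dissimilarity_matrix(cs, w, resample_ms=cfg.dtw_resample_ms)
            D.to_csv(out / "dissimilarity.csv")
            return {"n": len(D), "mean_dissimilarity": float(D.D[np.triu_indices(len(D), 1)].mean()), **(D.meta or {})}

        timed("dtw", _dtw)

    def load_D():
        return dtw.DissimilarityMatrix.from_csv(need(out / "dissimilarity.csv", "dtw.dissimilarity"))

    # --- ordinate -----------------------------------------------------------
    if "ordinate" in stages:
        def _ordinate():
            D = load_D()
            truth = load_truth().set_index("whistle_id")
            labels = [truth.loc[i, "ecotype"] for i in D.ids]
            coords, stress = ordination.nmmds(
                D, restarts=cfg.nmmds_restarts, seed=cfg.stage_seed("ordinate")
            )
            pd.DataFrame(coords, index=D.ids, columns=["dim1", "dim2"]).to_csv(out / "nmmds.csv")
            km = ordination.kmedoids_accuracy(D, labels, seed=cfg.stage_seed("ordinate"))
            return {
                "stress": stress,
                "kmedoids_accuracy": km["accuracy"],
                "kmedoids_confusion": km["confusion"].tolist(),
                "classes": km["classes"],
            }

        timed("ordinate", _ordinate)

    # --- mrpp + dispersion ---------------------------------------------------
    if "mrpp" in stages:
        def _mrpp():
            D = load_D()
            truth = load_truth().set_index("whistle_id")
            block = {}
            for name, col in (("ecotype", "ecotype"), ("group", "group_id")):
                groups = [str(truth.loc[i, col]) for i in D.ids]
                res = ordination.mrpp(
                    D, groups, n_perm=cfg.group_test_permutations, seed=cfg.stage_seed("mrpp")
                )
                disp = ordination.multivariate_dispersion(
                    D, groups, n_perm=cfg.group_test_permutations, seed=cfg.stage_seed("mrpp")
                )
                block[name] = {
                    "mrpp": dataclasses.asdict(res),
                    "dispersion": {
                        "F": disp.F_statistic,
                        "p": disp.p_value,
                        "per_group": disp.group_dispersion,
                    },
                }
            return block

        timed("mrpp", _mrpp)

    # --- categorize ----------------------------------------------------------
    if "categorize" in stages:
        def _categorize():
            cs = load_contours()
            truth = load_truth().set_index("whistle_id")
            cfg_art = art.ArtConfig(
                vigilance=cfg.vigilance,
                resample_ms=cfg.art_resample_ms,
                max_iterations=cfg.art_max_iterations,
                seed=cfg.stage_seed("categorize"),
            )
            rep = art.categorize(cs, cfg_art)
            rep.to_frame().to_csv(out / "repertoire.csv", index=False)
            labels = {w: str(truth.loc[w, "ecotype"]) for w in rep.assignment}
            comp = art.repertoire_composition(rep, labels)
            (out / "composition.json").write_text(json.dumps(_round(comp), indent=2, sort_keys=True))
            counts = pd.DataFrame(
                [
                    {
                        "category_id": c.category_id,
                        **{
                            e: sum(1 for w in c.member_ids if labels[w] == e)
                            for e in sorted(set(labels.values()))
                        },
                    }
                    for c in rep.categories
                ]
            )
            counts.to_csv(out / "category_counts.csv", index=False)
            return {
                "n_categories": comp["n_categories"],
                "converged": rep.converged,
                "n_iterations": rep.n_iterations,
                "sharing": comp["sharing"],
                "abundance_by_shape": comp["abundance_by_shape"],
            }

        timed("categorize", _categorize)

    # --- classify ------------------------------------------------------------
    if "classify" in stages:
        def _classify():
            feats = pd.read_csv(need(out / "features.csv", "features.features"))
            X = feats[list(rf.FEATURE_NAMES)]
            y = feats["ecotype"]
            screen = rf.correlation_screen(X)
            xtr, ytr, xte, yte = rf.stratified_split(
                X, y, train_frac=cfg.train_frac, seed=cfg.stage_seed("classify")
            )
            report, cm = rf.fit_and_evaluate(
                xtr,
                ytr,
                xte,
                yte,
                n_trees=cfg.n_trees,
                mtry_grid=cfg.mtry_grid,
                cv=(cfg.cv_folds, cfg.cv_repeats),
                seed=cfg.stage_seed("classify"),
            )
            cm.to_frame().to_csv(out / "confusion.csv")
            report.importance.to_csv(out / "importance.csv")
            pdp_rows = []
            for name, (grid, probs) in report.pdp.items():
                for g, p in zip(grid, probs):
                    pdp_rows.append({"feature": name, "value": g, "p_coastal": p})
            pd.DataFrame(pdp_rows).to_csv(out / "pdp.csv", index=False)
            return {
                "accuracy": report.accuracy,
                "ci95": list(report.ci95),
                "kappa": report.kappa,
                "oob_error": report.oob_error,
                "tuned_mtry": report.tuned_mtry,
                "n_train": len(xtr),
                "n_test": len(xte),
                "confusion": cm.counts.tolist(),
                "flagged_correlations": screen["flagged"],
                "top_mda": list(report.importance.sort_values("MDA", ascending=False).index[:3]),
            }

        timed("classify", _classify)

    # --- diversity ------------------------------------------------------------
    if "diversity" in stages:
        def _diversity():
            counts = pd.read_csv(need(out / "category_counts.csv", "categorize.category_counts"))
            ecotypes = [c for c in counts.columns if c != "category_id"]
            vecs = {
                e: diversity.AbundanceVector(
                    {str(r["category_id"]): int(r[e]) for _, r in counts.iterrows() if r[e] > 0}
                )
                for e in ecotypes
            }
            block: dict = {"per_ecotype": {}}
            for e, v in vecs.items():
                block["per_ecotype"][e] = {
                    "n": v.n,
                    "coverage": diversity.sample_coverage(v),
                    **{
                        f"q{q}": {
                            "observed": diversity.hill_observed(v, q),
                            "asymptotic": diversity.hill_asymptotic(v, q)[0],
                        }
                        for q in (0, 1, 2)
                    },
                }
            if len(ecotypes) == 2:
                a, b = (vecs[e] for e in ecotypes)
                block["similarity"] = diversity.horn_morisita(a, b)
                cat_counts = {
                    str(r["category_id"]): {e: int(r[e]) for e in ecotypes}
                    for _, r in counts.iterrows()
                }
                block["specificity"] = diversity.ecotype_specificity_test(
                    cat_counts,
                    n_perm=cfg.specificity_permutations,
                    seed=cfg.stage_seed("diversity"),
                )
                curves = {
                    e: diversity.coverage_re_curves(
                        v,
                        extrapolate_to=2 * min(x.n for x in vecs.values()),
                        ci_level=cfg.diversity_ci,
                        n_boot=cfg.diversity_bootstrap,
                        seed=cfg.stage_seed("diversity"),
                    )
                    for e, v in vecs.items()
                }
                rows = []
                for e, cs in curves.items():
                    for q, rec in cs.items():
                        for i in range(len(rec["m"])):
                            rows.append(
                                {
                                    "ecotype": e,
                                    "q": q,
                                    "m": int(rec["m"][i]),
                                    "coverage": rec["coverage"][i],
                                    "diversity": rec["diversity"][i],
                                    "lo": rec["lo"][i],
                                    "hi": rec["hi"][i],
                                }
                            )
                pd.DataFrame(rows).to_csv(out / "re_curves.csv", index=False)
            (out / "diversity.json").write_text(json.dumps(_round(block), indent=2, sort_keys=True))
            return block

        timed("diversity", _diversity)

    return summary


def make_report(bundle: dict) -> str:
    """Render the summary bundle as a human-readable text report."""
    required = {
        "ordinate": "ordination",
        "classify": "rf.confusion",
        "categorize": "repertoire",
        "diversity": "diversity",
    }
    missing = [tag for key, tag in required.items() if key not in bundle]
    if missing:
        raise ValueError(f"incomplete bundle, missing: {missing}")
    lines = ["Whistle repertoire analysis", "=" * 28, ""]
    km = bundle["ordinate"]
    lines += [
        "k-medoids clustering (rows = prediction, cols = reference "
        f"{km['classes']}): accuracy {km['kmedoids_accuracy'] * 100:.2f}%",
    ]
    for cls, row in zip(km["classes"], km["kmedoids_confusion"]):
        lines.append(f"  {cls:>9}: {row}")
    cl = bundle["classify"]
    lines += [
        "",
        f"Random forest: accuracy {cl['accuracy'] * 100:.2f}% "
        f"(95% CI {cl['ci95'][0] * 100:.2f}-{cl['ci95'][1] * 100:.2f}%), "
        f"kappa {cl['kappa']:.2f}, OOB error {cl['oob_error'] * 100:.2f}%, "
        f"mtry {cl['tuned_mtry']}",
    ]
    for cls, row in zip(km["classes"], cl["confusion"]):
        lines.append(f"  {cls:>9}: {row}")
    cat = bundle["categorize"]
    lines += [
        "",
        f"ART categorization: {cat['n_categories']} categories "
        f"(converged: {cat['converged']} in {cat['n_iterations']} passes)",
        f"  sharing: {cat['sharing']}",
    ]
    div = bundle["diversity"]
    lines += ["", "Hill diversity (observed / asymptotic):"]
    for e, rec in div["per_ecotype"].items():
        lines.append(
            f"  {e:>9}: q0 {rec['q0']['observed']:.1f}/{rec['q0']['asymptotic']:.1f}  "
            f"q1 {rec['q1']['observed']:.1f}/{rec['q1']['asymptotic']:.1f}  "
            f"q2 {rec['q2']['observed']:.1f}/{rec['q2']['asymptotic']:.1f}  "
            f"coverage {rec['coverage'] * 100:.1f}%"
        )
    if "similarity" in div:
        lines.append(
            f"  Horn {div['similarity']['horn'] * 100:.2f}%, "
            f"Morisita-Horn {div['similarity']['morisita_horn'] * 100:.2f}%"
        )
    if "specificity" in div:
        sp = div["specificity"]
        lines.append(
            f"  ecotype-specific categories: {sp['observed'] * 100:.2f}% observed vs "
            f"{sp['permuted_mean'] * 100:.2f}% permuted mean (p = {sp['p_value']:.4f})"
        )
    return "\n".join(lines) + "\n"
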