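"""End-to-end workflow orchestration.

Runs the full modeling chain — curate, prefilter, rational split, GFA
variable selection, exhaustive best-subset refinement, PLS with
LOO-chosen latent variables, the validation battery, applicability
domain, Y-randomization, PCA factor scores, and composite wine
prediction — persisting every intermediate artifact and a summary JSON.

A single run seed fans out deterministically to per-stage child seeds
through ``numpy.random.SeedSequence``, so any stage can be reproduced in
isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dataset_io, descriptor_prep, rational_split, gfa_selection
from . import subset_selection, pls_engine, validation_suite, composite_wine

logger = logging.getLogger("odorqspr")

__all__ = ["PipelineConfig", "run_pipeline", "run_study", "stage_seeds"]

_STAGES = ("split", "gfa", "randomization", "wines")


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one child seed (< 2^31) per randomized stage."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint64)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """All stage parameters plus optional file locations.

    Defaults mirror the study conditions: six clusters, a quarter of
    each cluster held out, four-term GFA genomes with mutation
    probability 0.5 and smoothness 1.0, six-descriptor best subsets,
    five models retained at each selection stage, 100 response
    permutations, and a 99% DModX confidence level.
    """

    compound_csv: Optional[str] = None
    descriptor_csv: Optional[str] = None
    wine_csv: Optional[str] = None
    out_dir: str = "odorqspr_run"
    delta_max: float = 1.0
    sd_min: float = descriptor_prep.SD_MIN_DEFAULT
    r_max: float = descriptor_prep.R_MAX_DEFAULT
    k_clusters: int = 6
    test_fraction: float = 0.25
    gfa_population: int = 100
    gfa_iterations: int = 5000
    gfa_p_mut: float = 0.5
    gfa_smoothness: float = 1.0
    gfa_initial_length: int = 4
    gfa_max_length: Optional[int] = None
    gfa_term_kind: str = "mixed"
    n_gfa_models: int = 5
    subset_size: int = 6
    n_subset_models: int = 5
    subset_ranking: str = "test"  # "test" (study protocol) or "internal"
    a_max: int = 5
    n_permutations: int = 100
    ad_alpha: float = 0.01
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key=value config file (``#`` starts a comment)."""
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls(), key)
            if value.lower() in ("none", ""):
                kwargs[key] = None
            elif isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int) and not isinstance(default, bool):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _term_table(terms: Sequence[gfa_selection.TermSpec], X: pd.DataFrame) -> pd.DataFrame:
    """Evaluate terms on raw descriptors: one column per term label."""
    return pd.DataFrame(
        {t.label: t.evaluate(X) for t in terms}, index=X.index
    )


def _internal_split(y: pd.Series, fraction: float = 0.25) -> tuple[list, list]:
    """Deterministic response-ranked systematic split of the training set."""
    step = int(round(1.0 / fraction))
    order = list(y.sort_values().index)
    valid = [cid for rank, cid in enumerate(order, start=1) if rank % step == 0]
    sub = [cid for cid in order if cid not in valid]
    return sub, valid


def run_study(
    y: pd.Series,
    X: descriptor_prep.DescriptorMatrix,
    cfg: PipelineConfig,
    wines: Optional[Sequence[composite_wine.WineComposition]] = None,
    out_dir: Optional[Path] = None,
) -> dict:
    """Run the modeling chain on an in-memory curated study.

    ``y`` is the curated log(OT) response indexed by compound id; ``X``
    the raw descriptor matrix over (at least) those compounds.  Returns
    the summary dict; when ``out_dir`` is given, every intermediate is
    persisted there as CSV/JSON.
    """
    seeds = stage_seeds(cfg.seed)
    artifacts: dict[str, object] = {}

    def persist(name: str, obj) -> None:
        artifacts[name] = obj
        if out_dir is None:
            return
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path.with_suffix(".csv"), index=False)
        else:
            with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
                json.dump(obj, fh, indent=2, default=str)

    # ------------------------------------------------------------------ filter
    ids = [i for i in y.index if i in X.data.index]
    if len(ids) < len(y):
        missing = sorted(set(y.index) - set(ids))
        raise ValueError(f"descriptor matrix lacks compounds {missing[:5]}...")
    y = y.loc[ids].astype(float)
    raw = descriptor_prep.DescriptorMatrix(data=X.data.loc[ids])
    logger.info("prefiltering %d descriptors on %d compounds", raw.shape[1], raw.shape[0])
    filtered = descriptor_prep.prefilter(raw, sd_min=cfg.sd_min, r_max=cfg.r_max)
    persist("filter_log", filtered.removal_log_frame())

    # ------------------------------------------------------------------- split
    scaled, _ = descriptor_prep.autoscale(filtered)
    clusters = rational_split.kmedoid(scaled, k=cfg.k_clusters, seed=seeds["split"])
    train_ids, test_ids = rational_split.assign_test(clusters, fraction=cfg.test_fraction)
    persist("clusters", clusters.report_frame())
    persist("split", rational_split.split_frame(train_ids, test_ids))
    logger.info("split: %d train / %d test", len(train_ids), len(test_ids))
    Xtr_raw = filtered.data.loc[train_ids]
    y_tr = y.loc[train_ids]

    # --------------------------------------------------------------------- GFA
    gfa_cfg = gfa_selection.GFAConfig(
        population_size=cfg.gfa_population,
        iterations=cfg.gfa_iterations,
        p_mut=cfg.gfa_p_mut,
        d=cfg.gfa_smoothness,
        initial_length=cfg.gfa_initial_length,
        max_length=cfg.gfa_max_length,
        term_kind=cfg.gfa_term_kind,
        seed=seeds["gfa"],
    )
    ranked = gfa_selection.evolve(Xtr_raw, y_tr.to_numpy(), gfa_cfg)
    persist("gfa_models", gfa_selection.model_report(ranked[: max(20, cfg.n_gfa_models)]))
    gfa_pool = gfa_selection.descriptor_pool(ranked, m=cfg.n_gfa_models)
    gfa_terms = gfa_selection.term_pool(ranked, m=cfg.n_gfa_models)
    # drop terms that are degenerate on the training rows (e.g. a spline
    # whose knot sits at the observed minimum truncates to all zeros) and,
    # of any near-collinear pair, the one from the lower-ranked model
    train_terms = _term_table(gfa_terms, Xtr_raw)
    ok = train_terms.std(ddof=1) > 1e-8
    gfa_terms = [t for t in gfa_terms if ok[t.label]]
    train_terms = train_terms.loc[:, ok]
    corr = np.abs(np.corrcoef(train_terms.to_numpy(), rowvar=False))
    keep = np.ones(len(gfa_terms), dtype=bool)
    for j in range(len(gfa_terms)):
        if keep[j]:
            for k2 in range(j + 1, len(gfa_terms)):
                if keep[k2] and corr[j, k2] >= 0.999:
                    keep[k2] = False
    gfa_terms = [t for t, flag in zip(gfa_terms, keep) if flag]
    logger.info("GFA pool: %d descriptors, %d usable terms", len(gfa_pool), len(gfa_terms))

    # ------------------------------------------------------------- best subset
    terms_all = _term_table(gfa_terms, filtered.data)
    if cfg.subset_ranking == "test":
        sub_train, sub_valid = train_ids, test_ids
    else:
        sub_train, sub_valid = _internal_split(y_tr)
    size = min(cfg.subset_size, terms_all.shape[1])
    subsets = subset_selection.enumerate_best_subsets(
        terms_all.loc[sub_train],
        y.loc[sub_train].to_numpy(),
        terms_all.loc[sub_valid],
        y.loc[sub_valid].to_numpy(),
        size=size,
    )
    persist("subset_ranking", subset_selection.ranking_frame(subsets[:50]))
    final_cols = subset_selection.final_pool(subsets, m=min(cfg.n_subset_models, len(subsets)))
    logger.info("final pool: %s", final_cols)

    # --------------------------------------------------------------------- PLS
    design = terms_all[final_cols]
    Xtr, Xte = design.loc[train_ids], design.loc[test_ids]
    # keep at least one residual X-dimension so DModX stays defined
    a_max = max(1, min(cfg.a_max, len(final_cols) - 1, len(train_ids) - 2))
    A, q2_by_lv = pls_engine.select_lv(Xtr, y_tr, a_max)
    model = pls_engine.fit_pls(Xtr, y_tr, A)
    persist("pls_coefficients", pd.DataFrame(
        {"term": ["(intercept)"] + final_cols,
         "coefficient": np.concatenate([[model.intercept_], model.coef_])}))
    persist("pls_scores", pd.DataFrame(
        model.T, columns=[f"t{a + 1}" for a in range(A)]).assign(id=train_ids))
    persist("pls_loadings", pd.DataFrame(
        model.P, columns=[f"p{a + 1}" for a in range(A)]).assign(term=final_cols))
    vip_scores = pls_engine.vip(model)
    persist("vip", pd.DataFrame({"term": final_cols, "vip": vip_scores})
            .sort_values("vip", ascending=False))

    # -------------------------------------------------------------- validation
    fitted = model.predict(Xtr)
    loo_pred = pls_engine.loo_predictions(Xtr, y_tr, A)
    pred_test = model.predict(Xte)
    y_te = y.loc[test_ids]
    r2, r2a, s, f_ratio = validation_suite.fit_stats(y_tr, fitted, len(final_cols))
    q2 = 1.0 - float(np.sum((y_tr - loo_pred) ** 2) / np.sum((y_tr - y_tr.mean()) ** 2))
    rm_loo = validation_suite.rm2_metrics(y_tr, loo_pred)
    rm_test = validation_suite.rm2_metrics(y_te, pred_test)
    r2pred, q2f2, ccc, rmsep = validation_suite.external_metrics(y_te, pred_test, y_tr.mean())
    y_range = float(y_tr.max() - y_tr.min())
    cls_tr, _ = validation_suite.mae_criteria(np.abs(y_tr - loo_pred), y_range)
    cls_te, _ = validation_suite.mae_criteria(np.abs(y_te - pred_test), y_range)
    gt = validation_suite.golbraikh_tropsha(y_te, pred_test)
    report = validation_suite.ValidationReport(
        n_train=len(train_ids), n_test=len(test_ids), n_descriptors=len(final_cols),
        lv=A, r2=r2, r2_adj=r2a, s=s, f_ratio=f_ratio, q2_loo=q2,
        rm2_loo_avg=rm_loo["rm2_avg"], delta_rm2_loo=rm_loo["delta_rm2"],
        mae_class_train=cls_tr, r2pred=r2pred, q2f2=q2f2, ccc=ccc, rmsep=rmsep,
        rm2_test_avg=rm_test["rm2_avg"], delta_rm2_test=rm_test["delta_rm2"],
        mae_class_test=cls_te, gt=gt,
    )
    report.evaluate_verdicts()
    if out_dir is not None:
        report.to_frame().to_csv(out_dir / "validation_report.csv", index=False)

    # --------------------------------------------------- applicability domain
    ad_train = pls_engine.dmodx(model, Xtr, alpha=cfg.ad_alpha)
    ad_test = pls_engine.dmodx(model, Xte, alpha=cfg.ad_alpha)
    persist("ad_train", ad_train.to_frame())
    persist("ad_test", ad_test.to_frame())

    # --------------------------------------------------------- randomization
    rand = pls_engine.y_randomization(
        Xtr, y_tr, A, n_perm=cfg.n_permutations, seed=seeds["randomization"])
    persist("randomization", rand.to_frame())

    # ------------------------------------------------------ PCA factor scores
    pca_summary = None
    n_half = min(10, len(train_ids) // 2)
    if n_half >= 2 and len(final_cols) >= 2:
        order = y_tr.sort_values()
        extremes = list(order.index[:n_half]) + list(order.index[-n_half:])
        scores, loadings, explained = pls_engine.pca_factor_scores(
            design.loc[extremes], n_factors=2, rotate=True)
        pca_df = pd.DataFrame(scores, columns=["factor1", "factor2"])
        pca_df.insert(0, "id", extremes)
        pca_df["group"] = ["low"] * n_half + ["high"] * n_half
        persist("pca_scores", pca_df)
        pca_summary = {"explained_variance": list(map(float, explained))}

    # ------------------------------------------------------------- composites
    composite_summary = None
    if wines:
        table = design  # spline-transformed model columns for all compounds
        wine_pred = composite_wine.predict_wines(model, wines, table)
        persist("composite_wines", wine_pred)
        composite_summary = {
            row.wine_id: float(row.composite_log_ot) for row in wine_pred.itertuples()
        }

    summary = {
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "n_compounds": len(ids),
        "n_descriptors_raw": X.data.shape[1],
        "n_descriptors_filtered": filtered.shape[1],
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "gfa_pool": gfa_pool,
        "final_descriptors": final_cols,
        "lv": A,
        "q2_by_lv": list(map(float, q2_by_lv)),
        "validation": json.loads(report.to_json()),
        "randomization": {
            "r2_intercept": rand.r2_intercept,
            "q2_intercept": rand.q2_intercept,
            "passed": rand.passed,
        },
        "ad": {
            "d_crit": ad_train.d_crit,
            "n_train_outside": int(np.sum(~ad_train.in_domain)),
            "n_test_outside": int(np.sum(~ad_test.in_domain)),
        },
        "pca": pca_summary,
        "composite_wines": composite_summary,
    }
    persist("summary", summary)
    # keep non-serialized handles for callers
    summary["_model"] = model
    summary["_report"] = report
    summary["_artifacts"] = artifacts
    return summary


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-based front end: read inputs per the config, run, persist."""
    if cfg.compound_csv is None or cfg.descriptor_csv is None:
        raise ValueError("compound_csv and descriptor_csv are required")
    out_dir = Path(cfg.out_dir)
    records = dataset_io.read_compound_table(cfg.compound_csv)
    if any(r.log_ot is None for r in records):
        curated = dataset_io.merge_sources(records, delta_max=cfg.delta_max)
        out_dir.mkdir(parents=True, exist_ok=True)
        dataset_io.write_curated(curated, out_dir / "curated.csv", out_dir / "curation_log.json")
        y = pd.Series({r.id: r.log_ot for r in curated.records})
    else:
        y = pd.Series({r.id: r.log_ot for r in records})
    X = descriptor_prep.DescriptorMatrix.from_csv(cfg.descriptor_csv)
    wines = composite_wine.read_wine_table(cfg.wine_csv) if cfg.wine_csv else None
    summary = run_study(y, X, cfg, wines=wines, out_dir=out_dir)
    return summary
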