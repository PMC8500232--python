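"""End-to-end orchestration: configuration, stage sequencing, reporting.

``run_full`` executes compound filtering -> population summaries ->
distance-based geographic statistics -> the non-detect eligibility gate ->
elastic-net / Boruta pre-selection -> selection-gradient estimation, writing
tidy CSV outputs, a manifest (seeds, config hash, package versions) and a
human-readable log.  Identical configuration and seed reproduce byte-
identical numeric outputs.  Every stage seed is derived from the base seed
and the stage name, so disabling one stage leaves the others' output
unchanged.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    ScentMatrix,
    Study,
    filter_compounds,
    load_study,
    relative_fitness,
    to_relative,
    total_emission,
    z_transform,
)
from .synthetic import SyntheticTruth, generate_study
from .community import bray_curtis, euclidean_1d, permanova_nested, rf_distinctness
from .nondetect import simulate_nondetect_bias, select_reliable_compounds, eligible_compounds
from .select import ElasticNetSelector, BorutaSelector, merge_candidates
from .gradients import SelectionGradientModel

log = logging.getLogger("scentsel")


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips through YAML unchanged."""

    # input: either delimited-text paths or an inline synthetic truth
    scent_path: str | None = None
    descriptor_path: str | None = None
    metadata_path: str | None = None
    fitness_path: str | None = None
    synthetic: dict | None = None

    # stage toggles
    do_geostats: bool = True
    do_eligibility: bool = True
    do_preselection: bool = True
    do_gradients: bool = True

    # parameters
    min_occurrence: int = 4
    n_perm: int = 9999
    rf_ntree: int = 1000
    rf_mtry: int = 17
    bias_n_rep: int = 100
    bias_grid_step: float = 0.05
    bias_planted_effect: float = 0.5
    max_relative_bias: float = 0.5
    min_selection_n: int = 30
    enet_l1_ratio: float = 0.5
    enet_cv: int = 10
    enet_lambda_rule: str = "1se"
    boruta_max_iter: int = 50
    boruta_alpha: float = 0.01
    boruta_trees: int = 100
    vif_strong: float = 10.0
    vif_moderate: float = 5.0
    cook_exclude: float = 1.0
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def _load_or_generate(config: RunConfig) -> Study:
    if config.synthetic is not None:
        d = dict(config.synthetic)
        d.setdefault("seed", config.stage_seed("synthetic"))
        if "populations" in d:
            d["populations"] = {
                r: [(p, int(n)) for p, n in pops]
                for r, pops in d["populations"].items()
            }
        for key in ("sigma_range", "flowers_range"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("beta", "gamma"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        truth = SyntheticTruth(**d)
        study, _ = generate_study(truth)
        return study
    if config.scent_path is None or config.descriptor_path is None:
        raise ValueError("config must provide input paths or a synthetic block")
    return load_study(
        config.scent_path,
        config.descriptor_path,
        fitness_path=config.fitness_path,
        metadata_path=config.metadata_path,
    )


def summarize_populations(matrix: ScentMatrix, samples: pd.DataFrame,
                          trace_threshold: float = 0.05
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population medians of total emission and relative amounts.

    Returns ``(summary, medians)``: the summary has one row per population
    (region, n, median total emission, compound count); the medians table is
    populations x compounds with median relative amounts (percent), where
    positive values below `trace_threshold` percent are rendered "tr".
    """
    if matrix.mode != "absolute":
        raise ValueError("summaries require an absolute-mode matrix")
    pops = samples.loc[matrix.sample_ids, "population"]
    if pops.isna().any():
        raise ValueError("samples missing population labels")
    rel = to_relative(matrix)
    tot = total_emission(matrix)
    rows, med_rows = [], {}
    for pop, idx in pops.groupby(pops).groups.items():
        sub = matrix.values.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"population {pop!r} is empty")
        rows.append(
            {
                "population": pop,
                "region": samples.loc[idx[0], "region"],
                "n_samples": len(idx),
                "median_total": float(tot.loc[idx, "total"].median()),
                "n_compounds": int((sub > 0).any(axis=0).sum()),
            }
        )
        med_rows[pop] = rel.values.loc[idx].median(axis=0)
    summary = pd.DataFrame(rows).set_index("population")
    medians = pd.DataFrame(med_rows).T
    medians.index.name = "population"

    def render(v: float) -> str:
        if v == 0:
            return "0"
        if v < trace_threshold:
            return "tr"
        return f"{v:.2f}"

    medians = medians.map(render)
    return summary, medians


def _selection_populations(study: Study, config: RunConfig) -> list[str]:
    if study.fitness is None:
        return []
    counts = study.samples.loc[
        study.samples["sample_type"] == "inflorescence", "population"
    ].value_counts()
    return [p for p, n in counts.items() if n >= config.min_selection_n]


def run_full(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every enabled stage; write outputs and a manifest under `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        return _run_stages(config, out, results)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, out: Path, results: dict) -> dict:
    def fail(stage: str, err: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    try:
        study = _load_or_generate(config)
    except Exception as e:  # noqa: BLE001
        fail("load", e)
    results["study"] = study
    infl = study.inflorescence()
    controls = study.controls()

    # ---- filtering -------------------------------------------------------
    try:
        filtered = filter_compounds(
            infl, controls if controls.n_samples else None,
            min_occurrence=config.min_occurrence,
        )
        dropped = sorted(set(infl.compound_ids) - set(filtered.compound_ids))
        log.info(
            "filter: retained %d/%d compounds (min_occurrence=%d); dropped %s",
            filtered.n_compounds, infl.n_compounds, config.min_occurrence, dropped,
        )
    except Exception as e:  # noqa: BLE001
        fail("filter", e)
    results["filtered"] = filtered

    # ---- summaries -------------------------------------------------------
    try:
        summary, medians = summarize_populations(filtered, study.samples)
        summary.to_csv(out / "population_summary.csv")
        medians.to_csv(out / "population_compound_medians.csv")
    except Exception as e:  # noqa: BLE001
        fail("summaries", e)
    results["summary"] = summary

    pops = study.samples.loc[filtered.sample_ids, "population"]
    regions = study.samples.loc[filtered.sample_ids, "region"]

    # ---- geographic statistics ------------------------------------------
    if config.do_geostats:
        try:
            results["permanova"] = {}
            tot = total_emission(filtered)
            datasets = {
                "bray_curtis_absolute": bray_curtis(filtered),
                "bray_curtis_relative": bray_curtis(to_relative(filtered)),
                "euclid_total": euclidean_1d(tot["total"]),
                "euclid_richness": euclidean_1d(tot["richness"]),
            }
            nested_ok = regions.nunique() >= 2 and (
                pops.groupby(regions).nunique().ge(2).any()
                and pops.nunique() > regions.nunique()
            )
            for name, dmat in datasets.items():
                res = permanova_nested(
                    dmat,
                    regions,
                    pops if nested_ok else None,
                    n_perm=config.n_perm,
                    seed=config.stage_seed(f"permanova:{name}"),
                )
                res.table.to_csv(out / f"permanova_{name}.csv")
                results["permanova"][name] = res
            if regions.nunique() >= 2:
                rf = rf_distinctness(
                    filtered, regions,
                    ntree=config.rf_ntree, mtry=config.rf_mtry,
                    seed=config.stage_seed("rf:region"),
                )
                rf.top.to_csv(out / "rf_region_importance.csv", index=False)
                pd.Series({"oob_error_pct": rf.oob_error}).to_csv(
                    out / "rf_region_oob.csv", header=False
                )
                results["rf_region"] = rf
        except Exception as e:  # noqa: BLE001
            fail("geostats", e)

    if study.fitness is None or not (
        config.do_eligibility or config.do_preselection or config.do_gradients
    ):
        _write_manifest(config, out)
        return results

    sel_pops = _selection_populations(study, config)
    log.info("selection analyses for populations: %s", sel_pops)
    fitness = relative_fitness(study.fitness, study.samples["population"])
    results["selection"] = {}

    for pop in sel_pops:
        ids = [s for s in filtered.sample_ids
               if pops[s] == pop and s in fitness.index]
        sub = filtered.subset_samples(ids)
        # drop compounds never seen in this population (cannot be standardised)
        present = [c for c in sub.compound_ids if (sub.values[c] > 0).any()
                   and sub.values[c].nunique() > 1]
        sub = sub.subset_compounds(present)
        w = fitness.loc[ids, "rel_fruit_set"]
        pop_res: dict = {"n": len(ids)}
        results["selection"][pop] = pop_res

        # ---- eligibility gate -------------------------------------------
        if config.do_eligibility:
            try:
                grid = np.arange(config.bias_grid_step, 1.0001,
                                 config.bias_grid_step)
                profile = simulate_nondetect_bias(
                    sub,
                    planted_effect=config.bias_planted_effect,
                    grid=grid,
                    n_rep=config.bias_n_rep,
                    seed=config.stage_seed(f"bias:{pop}"),
                )
                profile.table.to_csv(out / f"bias_profile_{pop}.csv")
                verdicts = select_reliable_compounds(
                    profile, sub, max_relative_bias=config.max_relative_bias
                )
                verdicts.to_csv(out / f"eligibility_{pop}.csv")
                eligible = eligible_compounds(verdicts)
                log.info("eligibility %s: %d/%d compounds pass",
                         pop, len(eligible), sub.n_compounds)
                pop_res["eligible"] = eligible
            except Exception as e:  # noqa: BLE001
                fail(f"eligibility:{pop}", e)
        else:
            eligible = list(sub.compound_ids)
            pop_res["eligible"] = eligible

        if not (config.do_preselection or config.do_gradients):
            continue
        if not eligible:
            log.info("%s: no eligible compounds; skipping selection analyses", pop)
            continue

        # ---- pre-selection ----------------------------------------------
        X = sub.values[eligible].copy()
        X["total_emission"] = total_emission(sub)["total"]
        X = X.loc[:, X.nunique() > 1]
        Z = z_transform(X)
        try:
            enet = ElasticNetSelector(
                l1_ratio=config.enet_l1_ratio,
                cv=min(config.enet_cv, len(ids)),
                lambda_rule=config.enet_lambda_rule,
                random_state=config.stage_seed(f"enet:{pop}"),
            ).fit(Z, w)
            boruta = BorutaSelector(
                n_estimators=config.boruta_trees,
                max_iter=config.boruta_max_iter,
                alpha_level=config.boruta_alpha,
                random_state=config.stage_seed(f"boruta:{pop}"),
            ).fit(Z, w)
            cands = merge_candidates(enet, boruta)
            log.info("preselection %s:\n%s", pop, cands.report())
            sel_table = pd.DataFrame(
                {
                    "compound": list(Z.columns),
                    "enet_coef": enet.coef_,
                    "enet_selected": enet.support_,
                    "boruta_status": boruta.status_.to_numpy(),
                }
            )
            sel_table.to_csv(out / f"selection_{pop}.csv", index=False)
            pop_res["candidates"] = cands
        except Exception as e:  # noqa: BLE001
            fail(f"preselection:{pop}", e)

        # ---- gradients ---------------------------------------------------
        if not config.do_gradients:
            continue
        # the fitness proxy never enters the gradient models as a trait
        linear_traits = [c for c in cands.linear if c != "total_emission"]
        nonlinear_traits = [c for c in cands.nonlinear if c != "total_emission"]
        tables = []
        try:
            if linear_traits:
                m = SelectionGradientModel(
                    quadratic=False,
                    strong_threshold=config.vif_strong,
                    moderate_threshold=config.vif_moderate,
                    cook_exclude=config.cook_exclude,
                ).fit(Z[linear_traits], w)
                t = m.gradients_.copy()
                t["model"] = "linear"
                tables.append(t)
                pop_res["linear_model"] = m
                _log_diagnostics(pop, "linear", m)
            if nonlinear_traits:
                m = SelectionGradientModel(
                    quadratic=True,
                    strong_threshold=config.vif_strong,
                    moderate_threshold=config.vif_moderate,
                    cook_exclude=config.cook_exclude,
                ).fit(Z[nonlinear_traits], w)
                t = m.gradients_.copy()
                t["model"] = "quadratic"
                tables.append(t)
                pop_res["quadratic_model"] = m
                _log_diagnostics(pop, "quadratic", m)
            if tables:
                pd.concat(tables).to_csv(out / f"gradients_{pop}.csv")
            else:
                log.info("%s: no candidates selected; gradient fitting skipped", pop)
                (out / f"gradients_{pop}.csv").write_text(
                    "term,type,estimate,se,t,p,significant,model\n"
                )
        except Exception as e:  # noqa: BLE001
            fail(f"gradients:{pop}", e)

    _write_manifest(config, out)
    return results


def _log_diagnostics(pop: str, kind: str, model: SelectionGradientModel) -> None:
    d = model.diagnostics_
    log.info(
        "%s %s model: adj_R2=%.3f max_VIF=%.2f substitutions=%s excluded=%s",
        pop, kind, d.adj_r2,
        float(d.vif.max()) if len(d.vif) else 1.0,
        d.substitutions, d.excluded,
    )


def _write_manifest(config: RunConfig, out: Path) -> None:
    manifest = {
        "package": "scentsel",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    config.to_yaml(out / "config.yaml")
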