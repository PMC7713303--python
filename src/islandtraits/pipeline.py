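"""End-to-end orchestration: classification -> pGLS -> model selection ->
rate shifts -> beta diversity, from one config file.

A :class:`RunConfig` either points at prepared inputs (Newick tree, posterior
multi-tree file, trait CSV, occurrence CSV, unit->realm CSV, clade CSV) or
embeds a synthetic scenario that the pipeline materializes first.  Stages run
in dependency order, every artifact is CSV/JSON, seeds are recorded, and a
rerun with the same config and seeds reproduces every table byte for byte
(the log line carrying the wall-clock timestamp is the only exception).

Artifacts written to the output directory::

    table1.csv       per-trait model comparison (AICc table)
    fig2_weights.csv mean +/- SE Akaike weights across posterior trees per clade
    pgls_tables.csv  pGLS F tests, coefficients and Tukey-style contrasts
    table2_rates.csv per-habitat and pairwise rate-shift results
    fig1c_beta.csv   pairwise PhyloSor partitions per scope
    sensitivity.csv  pGLS coefficient spread across posterior trees
    run.log          one structured line per stage with input hashes
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from islandtraits import beta_div, evomodels, pgls, rate_shift, synthetic_data
from islandtraits import trait_data
from islandtraits.errors import DataError, FitError, IslandTraitsError
from islandtraits.phylo import (
    Phylogeny,
    extract_clade,
    normalize_label,
    parse_newick,
    read_newick,
    write_newick,
)

__all__ = ["RunConfig", "run_pipeline", "summarize_report", "ARTIFACTS"]

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "table1.csv",
    "fig2_weights.csv",
    "pgls_tables.csv",
    "table2_rates.csv",
    "fig1c_beta.csv",
    "sensitivity.csv",
    "run.log",
)

HABITATS = trait_data.HABITATS


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: str
    seed: int = 0
    # prepared-input mode
    tree: str = None
    posterior_trees: str = None
    traits: str = None
    occurrences: str = None
    realm_map: str = None
    clades: str = None
    # synthetic mode
    scenario: dict = None
    # knobs
    trait_columns: tuple = ("log_height", "log_fruit_diameter")
    n_posterior: int = 20
    n_perm: int = 1000
    alpha: float = 0.05
    realms: tuple = ("global",)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path = Path(".")):
        if self.scenario is None:
            missing = []
            for key in ("tree", "traits", "occurrences", "realm_map"):
                p = getattr(self, key)
                if p is None:
                    missing.append(key)
                else:
                    full = (base / p) if not Path(p).is_absolute() else Path(p)
                    if not full.exists():
                        raise DataError(f"config path for {key} does not exist: {p}")
                    setattr(self, key, str(full))
            if missing:
                raise DataError(f"config lacks required paths: {missing}")
            for key in ("posterior_trees", "clades"):
                p = getattr(self, key)
                if p is not None:
                    full = (base / p) if not Path(p).is_absolute() else Path(p)
                    if not full.exists():
                        raise DataError(f"config path for {key} does not exist: {p}")
                    setattr(self, key, str(full))
        self.trait_columns = tuple(self.trait_columns)
        self.realms = tuple(self.realms)
        return self


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def _materialize_synthetic(cfg: RunConfig, out: Path):
    """Generate tree.nwk / traits.csv / occurrences.csv / realm_map.csv /
    posterior.nwk / truth.json from the embedded scenario."""
    sc = synthetic_data.SimScenario(**(cfg.scenario or {}))
    tree, habitat, tips, node_states, truth = synthetic_data.simulate_scenario(sc)
    rng = np.random.default_rng(np.random.SeedSequence((sc.seed, 101)))

    (out / "tree.nwk").write_text(write_newick(tree) + "\n")
    # second, weakly-shifted trait so both trait columns are exercised
    tips2, _ = synthetic_data.simulate_trait(
        tree, sc.trait_model, sc.trait_params,
        seed=np.random.default_rng(np.random.SeedSequence((sc.seed, 102))))
    traits = pd.DataFrame({
        "species": list(tree.tip_labels),
        "height": [10.0 ** tips[l] for l in tree.tip_labels],
        "fruit_diameter": [10.0 ** tips2[l] for l in tree.tip_labels],
    })
    _write_csv(traits, out / "traits.csv")

    realms = list(trait_data.REALMS)
    unit_rows, occ_rows = [], []
    for r in realms:
        short = r.split("/")[0][:5]
        for h in HABITATS:
            unit_rows.append({"unit": f"{short}_{h}", "realm": r})
    sp_realm = {l: realms[rng.integers(len(realms))] for l in tree.tip_labels}
    for lab in tree.tip_labels:
        r = sp_realm[lab]
        short = r.split("/")[0][:5]
        h = habitat[lab]
        if h == "widespread":
            # widespread = records in two habitat categories
            h1, h2 = rng.choice(len(HABITATS), size=2, replace=False)
            occ_rows.append({"species": lab, "unit": f"{short}_{HABITATS[h1]}",
                             "unit_class": HABITATS[h1]})
            occ_rows.append({"species": lab, "unit": f"{short}_{HABITATS[h2]}",
                             "unit_class": HABITATS[h2]})
        else:
            occ_rows.append({"species": lab, "unit": f"{short}_{h}",
                             "unit_class": h})
    _write_csv(pd.DataFrame(occ_rows), out / "occurrences.csv")
    _write_csv(pd.DataFrame(unit_rows), out / "realm_map.csv")

    post = []
    for i in range(cfg.n_posterior):
        t = synthetic_data.simulate_tree(
            sc.n_tips, sc.birth, sc.death,
            seed=np.random.default_rng(np.random.SeedSequence((sc.seed, 200 + i))))
        post.append(write_newick(t))
    (out / "posterior.nwk").write_text("\n".join(post) + "\n")
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))

    cfg.tree = str(out / "tree.nwk")
    cfg.traits = str(out / "traits.csv")
    cfg.occurrences = str(out / "occurrences.csv")
    cfg.realm_map = str(out / "realm_map.csv")
    cfg.posterior_trees = str(out / "posterior.nwk")


# ---------------------------------------------------------------------------
# stages


def _stage_classify(cfg, state):
    occ = pd.read_csv(cfg.occurrences)
    rmap = pd.read_csv(cfg.realm_map)
    realm_map = dict(zip(rmap["unit"], rmap["realm"]))
    state["habitat_df"] = trait_data.classify_habitat(occ, realm_map)
    state["traits"] = trait_data.load_traits(cfg.traits)


def _trait_maps(cfg, state):
    tt = state["traits"]
    for col in cfg.trait_columns:
        if col in tt.data.columns:
            yield col, tt.trait(col)


def _aligned(tree, trait_map, habitat_df, exclude_widespread=True):
    hab = dict(zip(habitat_df["species"], habitat_df["habitat"]))
    rows = []
    for lab in tree.tip_labels:
        key = normalize_label(lab)
        if key in trait_map and key in hab:
            if exclude_widespread and hab[key] == "widespread":
                continue
            rows.append((lab, trait_map[key], hab[key]))
    if len(rows) < 10:
        raise FitError(f"only {len(rows)} species align across tree/traits/habitat")
    labs = [r[0] for r in rows]
    sub = extract_clade(tree, labs)
    lut = {normalize_label(l): (v, h) for l, v, h in rows}
    y = np.array([lut[normalize_label(l)][0] for l in sub.tip_labels])
    habs = [lut[normalize_label(l)][1] for l in sub.tip_labels]
    return sub, y, habs


def _stage_pgls(cfg, state):
    tree = state["tree"]
    out_rows = []
    contrasts_by_trait = {}
    for col, tmap in _trait_maps(cfg, state):
        sub, y, habs = _aligned(tree, tmap, state["habitat_df"])
        levels = [h for h in HABITATS if h in set(habs)]
        X = pgls.design_matrix(habs, levels=levels)
        full = pgls.fit_pgls(y, X, tree=sub)
        red = pgls.fit_pgls(y, X[["Intercept"]], tree=sub)
        ft = pgls.anova_f(full, red)
        out_rows.append({"trait": col, "section": "ftest", "term": "habitat",
                         "estimate": ft.F, "se": np.nan, "stat": ft.F,
                         "df1": ft.df1, "df2": ft.df2, "p": ft.p_value,
                         "letters": "", "n": full.n})
        ct = full.coef_table()
        for name, row in ct.iterrows():
            out_rows.append({"trait": col, "section": "coef", "term": name,
                             "estimate": row["coef"], "se": row["se"],
                             "stat": row["t"], "df1": np.nan,
                             "df2": full.df_resid, "p": row["p"],
                             "letters": "", "n": full.n})
        if ft.p_value < cfg.alpha and len(levels) >= 2:
            cs = pgls.pairwise_contrasts(full, levels, seed=cfg.seed)
            contrasts_by_trait[col] = cs
            for (a, b), est, se, st, pa in zip(cs.pairs, cs.estimate, cs.se,
                                               cs.statistic, cs.p_adjusted):
                out_rows.append({"trait": col, "section": "contrast",
                                 "term": f"{a} - {b}", "estimate": est,
                                 "se": se, "stat": st, "df1": np.nan,
                                 "df2": full.df_resid, "p": pa,
                                 "letters": f"{cs.letters[a]}/{cs.letters[b]}",
                                 "n": full.n})
        state.setdefault("pgls_fits", {})[col] = (sub, y, habs, full, red, ft)
    state["pgls_rows"] = out_rows
    state["contrasts"] = contrasts_by_trait
    _write_csv(pd.DataFrame(out_rows), state["out"] / "pgls_tables.csv")


def _stage_models(cfg, state):
    tree = state["tree"]
    rows = []
    for col, tmap in _trait_maps(cfg, state):
        comp = evomodels.model_table(tree, tmap)
        for r in comp.to_rows():
            r["trait"] = col
            rows.append(r)
        state.setdefault("model_comparisons", {})[col] = comp
    _write_csv(pd.DataFrame(rows)[["trait", "model", "delta_AICc", "lnL", "k",
                                   "AICc", "weight"]],
               state["out"] / "table1.csv")

    # per-clade mean Akaike weights across the posterior sample; without a
    # clade table the whole tip set acts as the single clade
    rows2 = []
    if state.get("posterior"):
        trees = state["posterior"]
        clades = {"all": None}
        if cfg.clades:
            cdf = pd.read_csv(cfg.clades)
            clades = {name: set(grp["species"])
                      for name, grp in cdf.groupby("clade")}
        for col, tmap in _trait_maps(cfg, state):
            for cname, taxa in clades.items():
                cmap = tmap if taxa is None else {
                    k: v for k, v in tmap.items() if normalize_label(k) in
                    {normalize_label(t) for t in taxa}}
                if taxa is not None and len(cmap) < 10:
                    continue  # too few species with data for this trait
                try:
                    mt = evomodels.fit_across_trees(trees, cmap)
                except FitError:
                    continue
                for m in mt.models:
                    rows2.append({"trait": col, "clade": cname, "model": m,
                                  "mean_weight": mt.mean_weight[m],
                                  "se_weight": mt.se_weight[m],
                                  "n_trees": mt.n_trees})
    _write_csv(pd.DataFrame(rows2), state["out"] / "fig2_weights.csv")


def _stage_rates(cfg, state):
    tree = state["tree"]
    rows = []
    for col, tmap in _trait_maps(cfg, state):
        sub, y, habs = _aligned(tree, tmap, state["habitat_df"])
        lam = rate_shift.optimize_lambda(sub, y)
        fit = rate_shift.ridge_rates(sub, y, lam)
        states = dict(zip(sub.tip_labels, habs))
        st = rate_shift.search_shift_state(sub, fit, states,
                                           n_perm=cfg.n_perm, seed=cfg.seed)
        for s, (d, p, v) in st.state_results.items():
            rows.append({"trait": col, "comparison": s, "kind": "state",
                         "rate_difference": d, "p": p, "verdict": v,
                         "lambda": lam, "n": sub.n_tips})
        for (a, b), (d, p, v) in st.pairwise.items():
            rows.append({"trait": col, "comparison": f"{a} - {b}",
                         "kind": "pairwise", "rate_difference": d, "p": p,
                         "verdict": v, "lambda": lam, "n": sub.n_tips})
    _write_csv(pd.DataFrame(rows), state["out"] / "table2_rates.csv")
    state["rate_rows"] = rows


def _stage_beta(cfg, state):
    tree = state["tree"]
    hdf = state["habitat_df"]
    rows = []
    scopes = [("global", hdf["habitat"])]
    for realm in sorted(set(hdf["realm"].dropna())):
        mask = hdf["realm"] == realm
        scopes.append((realm, hdf["realm_habitat"].where(mask)))
    tipset = {normalize_label(l) for l in tree.tip_labels}
    for scope, habcol in scopes:
        assemblages = {}
        for h in HABITATS:
            sp = set(hdf.loc[habcol == h, "species"]) & tipset
            if len(sp) >= 2:
                assemblages[h] = sp
        if len(assemblages) < 2:
            continue
        part = beta_div.phylosor_partition(tree, assemblages)
        for (a, b), bp in part.items():
            rows.append({"scope": scope, "pair": f"{a} - {b}",
                         "beta_sor": bp.beta_sor, "beta_sim": bp.beta_sim,
                         "beta_sne": bp.beta_sne, "dominant": bp.dominant})
    _write_csv(pd.DataFrame(rows), state["out"] / "fig1c_beta.csv")
    state["beta_rows"] = rows


def _stage_sensitivity(cfg, state):
    rows = []
    if state.get("posterior") and state.get("pgls_fits"):
        common = state["posterior"]
        for col, (sub, y, habs, full, red, ft) in state["pgls_fits"].items():
            # prune every posterior tree to the analysis tips
            trees = []
            for t in common:
                try:
                    trees.append(extract_clade(t, list(sub.tip_labels)))
                except IslandTraitsError:
                    continue
            if len(trees) < 2:
                continue
            levels = [h for h in HABITATS if h in set(habs)]
            X = pgls.design_matrix(habs, levels=levels)
            sens = pgls.tree_sensitivity(trees, y, X, X[["Intercept"]],
                                         alpha=cfg.alpha)
            for name, r in sens.coef_stats.iterrows():
                rows.append({"trait": col, "coef": name, "mean": r["mean"],
                             "sd": r["sd"], "min": r["min"], "max": r["max"],
                             "prop_significant": sens.prop_significant,
                             "sensitive": sens.sensitive,
                             "n_trees": sens.n_trees})
    _write_csv(pd.DataFrame(rows), state["out"] / "sensitivity.csv")


STAGES = (
    ("classify", _stage_classify),
    ("pgls", _stage_pgls),
    ("models", _stage_models),
    ("rates", _stage_rates),
    ("beta", _stage_beta),
    ("sensitivity", _stage_sensitivity),
)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; artifacts land in ``config.output_dir``.

    A stage failure is recorded in ``failure_manifest.json`` (completed
    artifacts are kept) and re-raised after the remaining independent stages
    were attempted is NOT done — stages run strictly in order and the first
    failure aborts, matching the dependency chain.
    """
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"# islandtraits run, seed={cfg.seed}"]
    log_lines.append(f"timestamp {time.strftime('%Y-%m-%dT%H:%M:%S')}")

    state = {"out": out}
    current = "setup"
    try:
        if cfg.scenario is not None:
            current = "synthesize"
            _materialize_synthetic(cfg, out)
            log_lines.append("stage=synthesize ok")
        current = "load"
        state["tree"] = read_newick(cfg.tree)
        if isinstance(state["tree"], list):
            raise DataError("main tree file must contain exactly one tree")
        if cfg.posterior_trees:
            post = read_newick(cfg.posterior_trees)
            state["posterior"] = post if isinstance(post, list) else [post]
        for key in ("tree", "traits", "occurrences", "realm_map",
                    "posterior_trees", "clades"):
            p = getattr(cfg, key)
            if p:
                log_lines.append(f"input {key}={p} sha256={_hash_file(p)}")
        for name, fn in STAGES:
            current = name
            fn(cfg, state)
            log_lines.append(f"stage={name} ok")
    except Exception as exc:
        manifest = {"failed_stage": current,
                    "error": f"{type(exc).__name__}: {exc}"}
        (out / "failure_manifest.json").write_text(json.dumps(manifest, indent=1))
        log_lines.append(f"stage={current} FAILED: {manifest['error']}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


# ---------------------------------------------------------------------------
# summary


def summarize_report(bundle_dir) -> str:
    """One-page text summary of a completed report bundle."""
    out = Path(bundle_dir)
    missing = [a for a in ARTIFACTS if not (out / a).exists()]
    if missing:
        raise DataError(f"incomplete bundle, missing artifacts: {missing}")
    lines = ["islandtraits report", "=" * 40]

    t1 = pd.read_csv(out / "table1.csv")
    lines.append("\nModel selection (AICc):")
    for trait, grp in t1.groupby("trait"):
        supported = grp[grp["delta_AICc"] <= 2.0]["model"].tolist()
        lines.append(f"  {trait}: supported model(s) {', '.join(supported)}")

    pg = pd.read_csv(out / "pgls_tables.csv")
    lines.append("\npGLS habitat effects:")
    for trait, grp in pg.groupby("trait"):
        ft = grp[grp["section"] == "ftest"].iloc[0]
        lines.append(f"  {trait}: F_{int(ft['df1'])},{int(ft['df2'])} = "
                     f"{ft['stat']:.3f}, p = {ft['p']:.4g}, n = {int(ft['n'])}")
        con = grp[grp["section"] == "contrast"]
        if len(con) == 0:
            lines.append("    no significant habitat effect; contrasts not run")
        for _, r in con.iterrows():
            flag = "*" if r["p"] < 0.05 else " "
            lines.append(f"    {r['term']}: {r['estimate']:+.3f} "
                         f"(p_adj = {r['p']:.4g}){flag} letters {r['letters']}")

    t2 = pd.read_csv(out / "table2_rates.csv")
    lines.append("\nRate shifts (p > 0.975 increase / p < 0.025 decrease):")
    for _, r in t2.iterrows():
        mark = {"increase": "+", "decrease": "-", "none": " "}[r["verdict"]]
        lines.append(f"  {r['trait']} {r['comparison']}: "
                     f"{r['rate_difference']:+.3f} (p = {r['p']:.3f}){mark}")

    bt = pd.read_csv(out / "fig1c_beta.csv")
    lines.append("\nPhylogenetic beta diversity (PhyloSor):")
    for _, r in bt.iterrows():
        lines.append(f"  [{r['scope']}] {r['pair']}: beta_sor = "
                     f"{r['beta_sor']:.3f} (dominant: {r['dominant']})")
    return "\n".join(lines)
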