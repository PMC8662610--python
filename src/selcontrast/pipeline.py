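"""Study orchestration: alignment prep -> model fits -> statistics -> tables.

``run_study`` drives the full analysis over a study directory (typically
written by :func:`selcontrast.simulate.generate_study`): every orthogroup is
prepared (back-translation, column trimming, sequence/alignment filters,
species-tree pruning), fitted under the requested model families, and the
statistical contrast layer is computed — LRTs with q-values per family,
Kruskal-Wallis + DSCF across annotation groups, omega-pattern splits,
expected-distribution chi-square tests, selection-intensity direction
splits, codon-usage bias and the expression-omega correlation.  Fits are
cached as JSON per orthogroup so interrupted runs resume.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .alignment import (
    Rejection,
    backtranslate,
    drop_short_sequences,
    trim_columns_by_score,
    validate_codon_alignment,
)
from .models import (
    BranchOmegaModel,
    BranchSiteModel,
    RelaxModel,
    SingleOmegaModel,
    MissingPartitionError,
    site_posteriors,
)
from .orthogroup import OrthoGroup
from .seqio import AnnotationTable, ensure_dir, read_column_scores, read_fasta
from .stats import (
    ContrastTable,
    chi_square_expected,
    classify_omega_pattern,
    codon_counts,
    codon_usage_bias_b,
    dscf_posthoc,
    kruskal_wallis,
    lrt,
    qvalues,
    spearman,
)
from .trees import LabeledTree, count_independent_transitions, prune_species_tree, species_of

GROUPS = ("testis-region", "ovary-region", "tail-region", "ubiquitous")
CONTRASTS = ("present-absent", "present-reduced")
_DERIVED = {"present-absent": "absent", "present-reduced": "reduced"}
_EVENT = {"present-absent": "loss", "present-reduced": "reduction"}


@dataclass
class StudyConfig:
    study_dir: str
    out_dir: str
    contrasts: tuple = CONTRASTS
    models: tuple = ("m0", "branch3", "modelA", "relax")
    alpha: float = 0.05
    score_threshold: float = 3.0
    min_fraction: float = 0.5
    min_transitions: int = 3
    branch_site_df: int = 2  # the reported convention; 1 is the usual choice
    fit_pdm: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["contrasts"] = tuple(data.get("contrasts", CONTRASTS))
        data["models"] = tuple(data.get("models", ("m0", "branch3", "modelA", "relax")))
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()}, fh)


@dataclass
class StudyReport:
    branch: pd.DataFrame
    branch_site: dict[str, pd.DataFrame]
    relax: dict[str, pd.DataFrame]
    tests: dict
    run_log: pd.DataFrame
    out_dir: str


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

def prepare_orthogroup(
    og_id: str,
    aa_path,
    cds_path,
    scores_path,
    species_tree: LabeledTree,
    annotation: AnnotationTable,
    *,
    score_threshold: float = 3.0,
    min_fraction: float = 0.5,
):
    """Alignment-prep cascade for one orthogroup.

    Returns an OrthoGroup, or a Rejection carrying the rule that failed.
    The fixed order — back-translate, column-trim, drop short sequences,
    validate, prune tree — is part of the contract (permuting the trim and
    drop steps changes results).
    """
    aa = read_fasta(aa_path)
    cds = read_fasta(cds_path)
    aln = backtranslate(aa, cds)
    scores = read_column_scores(scores_path)
    aln = trim_columns_by_score(aln, scores, threshold=score_threshold)
    aln = drop_short_sequences(aln, min_fraction=min_fraction)
    validated = validate_codon_alignment(aln)
    if isinstance(validated, Rejection):
        return validated
    species = [species_of(t) for t in validated.taxa]
    if len(set(species)) != len(species):
        return Rejection("duplicate_species", detail=og_id)
    renamed = validated.select_taxa(list(validated.taxa))
    renamed.taxa = species
    tree = prune_species_tree(species_tree, species)
    group = None
    for transcript, g in annotation.group.items():
        if transcript.endswith(f"@{og_id}"):
            group = g
            break
    og = OrthoGroup(
        og_id=og_id,
        alignment=renamed,
        tree=tree,
        annotation_group=group,
        n_independent_losses=count_independent_transitions(species, species_tree, "loss"),
        n_independent_reductions=count_independent_transitions(species, species_tree, "reduction"),
    )
    return og


def load_study(study_dir: str):
    """Read a study directory: labeled species tree, annotation, OG files."""
    species_tree = LabeledTree.from_newick(os.path.join(study_dir, "species_tree.nwk"))
    species_tree.traits = LabeledTree.read_traits(os.path.join(study_dir, "traits.tsv"))
    species_tree.transitions = LabeledTree.read_transitions(
        os.path.join(study_dir, "transitions.tsv")
    )
    annotation = AnnotationTable.read(os.path.join(study_dir, "annotation.tsv"))
    ogdir = os.path.join(study_dir, "ogs")
    og_ids = sorted(
        f[: -len(".aa.fasta")] for f in os.listdir(ogdir) if f.endswith(".aa.fasta")
    )
    files = {
        og: (
            os.path.join(ogdir, f"{og}.aa.fasta"),
            os.path.join(ogdir, f"{og}.cds.fasta"),
            os.path.join(ogdir, f"{og}.scores.tsv"),
        )
        for og in og_ids
    }
    return species_tree, annotation, files


# ---------------------------------------------------------------------------
# fitting one orthogroup
# ---------------------------------------------------------------------------

def _fit_orthogroup(og: OrthoGroup, config: StudyConfig, seed: int) -> dict:
    """All requested fits and LRTs for one orthogroup (JSON-serializable)."""
    rec: dict = {"og_id": og.og_id, "group": og.annotation_group,
                 "n_taxa": og.alignment.n_taxa, "n_columns": og.alignment.n_columns,
                 "n_losses": og.n_independent_losses,
                 "n_reductions": og.n_independent_reductions}
    m0 = SingleOmegaModel(og.alignment, og.tree).fit(seed=seed)
    rec["m0"] = m0.to_dict()
    if "branch3" in config.models:
        try:
            from .models import fit_branch_three_omega

            b3 = fit_branch_three_omega(og, start_from=m0, seed=seed)
            test = lrt(m0.lnL, b3.lnL, df=2)
            rec["branch3"] = b3.to_dict()
            rec["branch3"]["lrt_p"] = test.p
            rec["branch3"]["lrt_stat"] = test.statistic
        except MissingPartitionError as err:
            rec["branch3"] = {"skipped": str(err)}
    for contrast in config.contrasts:
        derived = _DERIVED[contrast]
        if "modelA" in config.models:
            rec[f"modelA:{contrast}"] = _fit_branch_site(og, contrast, derived, config, seed)
        if "relax" in config.models:
            rec[f"relax:{contrast}"] = _fit_relax(og, contrast, derived, config, seed)
    return rec


def _fit_branch_site(og, contrast, derived, config, seed):
    from .models import fit_model_a, fit_model_a_null

    try:
        null = fit_model_a_null(og, derived, seed=seed)
        alt = fit_model_a(og, derived, start_from=null, seed=seed)
    except MissingPartitionError as err:
        return {"skipped": str(err)}
    test = lrt(null.lnL, alt.lnL, df=config.branch_site_df)
    out = {"null": null.to_dict(), "alt": alt.to_dict(),
           "lrt_p": test.p, "lrt_stat": test.statistic, "df": config.branch_site_df}
    if alt.params["omega2"] > 1:
        _, flagged = site_posteriors(alt)
        out["n_flagged_sites"] = int(flagged.size)
        out["flagged_sites"] = [int(s) for s in flagged]
    else:
        out["n_flagged_sites"] = 0
        out["flagged_sites"] = []
    return out


def _fit_relax(og, contrast, derived, config, seed):
    from .models import fit_relax, fit_relax_pdm

    try:
        null = fit_relax(og, derived, fix_k=1.0, seed=seed)
        alt = fit_relax(og, derived, start_from=null, seed=seed)
    except MissingPartitionError as err:
        return {"skipped": str(err)}
    test = lrt(null.lnL, alt.lnL, df=1)
    out = {"null": null.to_dict(), "alt": alt.to_dict(),
           "lrt_p": test.p, "lrt_stat": test.statistic, "k": alt.params["k"]}
    if config.fit_pdm:
        out["pdm"] = fit_relax_pdm(og, derived, start_from=alt, seed=seed).to_dict()
    return out


# ---------------------------------------------------------------------------
# statistics over all orthogroups
# ---------------------------------------------------------------------------

def _contrast_chi2(df, sig_col, alpha, tests, label):
    """Observed-significant versus all-tested chi-square per annotation group."""
    tested = df.dropna(subset=[sig_col])
    counts = {
        g: (int((tested[tested.group == g][sig_col] < alpha).sum()),
            int((tested.group == g).sum()))
        for g in GROUPS
    }
    groups = [g for g in GROUPS if counts[g][1] > 0]
    observed = [counts[g][0] for g in groups]
    total = [counts[g][1] for g in groups]
    table = ContrastTable(groups=groups, observed=np.array(observed), total=np.array(total))
    tests[label + "_table"] = {
        "groups": groups, "observed": observed, "total": total,
        "percent": [round(p, 1) for p in table.percent],
    }
    if sum(observed) > 0 and len(groups) >= 2:
        res = chi_square_expected(table)
        tests[label + "_chi2"] = {"statistic": res.statistic, "df": res.df, "p": res.p}
    return table


def stratify_by_transitions(df: pd.DataFrame, min_transitions: int = 3,
                            column: str = "n_losses") -> pd.DataFrame:
    """Keep orthogroups covering at least ``min_transitions`` independent
    trait transitions (idempotent; 0 is the identity)."""
    if min_transitions <= 0:
        return df
    return df[df[column] >= min_transitions].copy()


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full analysis; see module docstring for the stages."""
    species_tree, annotation, files = load_study(config.study_dir)
    out_dir = ensure_dir(config.out_dir)
    fits_dir = ensure_dir(os.path.join(out_dir, "fits"))

    run_log = []
    records = []
    for index, (og_id, (aa_path, cds_path, scores_path)) in enumerate(sorted(files.items())):
        cache = os.path.join(fits_dir, f"{og_id}.json")
        if os.path.exists(cache):
            with open(cache) as fh:
                records.append(json.load(fh))
            run_log.append({"og_id": og_id, "status": "analyzed", "reason": "cached"})
            continue
        prepared = prepare_orthogroup(
            og_id, aa_path, cds_path, scores_path, species_tree, annotation,
            score_threshold=config.score_threshold, min_fraction=config.min_fraction,
        )
        if isinstance(prepared, Rejection):
            run_log.append({"og_id": og_id, "status": "excluded", "reason": prepared.rule})
            continue
        seed = (config.seed * 100003 + index) % (2**31 - 1)
        rec = _fit_orthogroup(prepared, config, seed)
        rec["expression"] = _expression_of(annotation, og_id)
        rec["codon_bias_absent"] = _codon_bias(prepared)
        with open(cache, "w") as fh:
            json.dump(rec, fh)
        records.append(rec)
        run_log.append({"og_id": og_id, "status": "analyzed", "reason": ""})

    report = summarize(records, config, out_dir)
    report.run_log = pd.DataFrame(run_log)
    report.run_log.to_csv(os.path.join(out_dir, "run_log.tsv"), sep="\t", index=False)
    return report


def _expression_of(annotation, og_id):
    for transcript, value in annotation.expression.items():
        if transcript.endswith(f"@{og_id}"):
            return float(value)
    return None


def _codon_bias(og: OrthoGroup):
    """Mean codon-usage bias of absent-bristle species against the
    bristles-present reference set of the same alignment."""
    absent = [t for t in og.taxa if og.tree.state_of(t) == "absent"]
    present = [t for t in og.taxa if og.tree.state_of(t) == "present"]
    if not absent or not present:
        return None
    ref = codon_counts(og.alignment, present)
    values = []
    for t in absent:
        gene = codon_counts(og.alignment, [t])
        if not gene:
            continue
        try:
            values.append(codon_usage_bias_b(gene, ref, og.alignment.code))
        except ValueError:
            continue
    return float(np.mean(values)) if values else None


def summarize(records: list[dict], config: StudyConfig, out_dir: str) -> StudyReport:
    """Statistics layer over the per-orthogroup fit records."""
    tests: dict = {}
    rows = []
    for rec in records:
        row = {
            "og_id": rec["og_id"], "group": rec["group"],
            "n_taxa": rec["n_taxa"], "n_columns": rec["n_columns"],
            "n_losses": rec["n_losses"], "n_reductions": rec["n_reductions"],
            "omega_m0": rec["m0"]["params"]["omega"],
            "kappa_m0": rec["m0"]["params"]["kappa"],
            "lnl_m0": rec["m0"]["lnL"],
            "expression": rec.get("expression"),
            "codon_bias_absent": rec.get("codon_bias_absent"),
        }
        b3 = rec.get("branch3")
        if b3 and "skipped" not in b3:
            labels = b3["params"]["labels"]
            omegas = dict(zip(labels, b3["params"]["omega_by_label"]))
            row.update(
                omega_present=omegas.get(0), omega_reduced=omegas.get(1),
                omega_absent=omegas.get(2), lnl_branch3=b3["lnL"],
                p_branch=b3["lrt_p"],
            )
            if all(k in omegas for k in (0, 1, 2)):
                coarse, fine, _ = classify_omega_pattern(omegas[0], omegas[1], omegas[2])
                row["pattern_coarse"] = coarse
                row["pattern_fine"] = fine
        for contrast in config.contrasts:
            short = "pa" if contrast == "present-absent" else "pr"
            bs = rec.get(f"modelA:{contrast}")
            if bs and "skipped" not in bs:
                row[f"p_bs_{short}"] = bs["lrt_p"]
                row[f"omega2_{short}"] = bs["alt"]["params"]["omega2"]
                row[f"n_sites_{short}"] = bs["n_flagged_sites"]
            rl = rec.get(f"relax:{contrast}")
            if rl and "skipped" not in rl:
                row[f"p_relax_{short}"] = rl["lrt_p"]
                row[f"k_{short}"] = rl["k"]
        rows.append(row)
    df = pd.DataFrame(rows)

    # q-values per model family
    for col, qcol in [("p_branch", "q_branch"), ("p_bs_pa", "q_bs_pa"),
                      ("p_bs_pr", "q_bs_pr"), ("p_relax_pa", "q_relax_pa"),
                      ("p_relax_pr", "q_relax_pr")]:
        if col in df.columns:
            mask = df[col].notna()
            if mask.sum() >= 2:
                q, pi0 = qvalues(df.loc[mask, col].to_numpy())
                df.loc[mask, qcol] = q
                tests[f"pi0_{col}"] = pi0

    # KW + DSCF of single-omega estimates across annotation groups
    by_group = [df[df.group == g]["omega_m0"].dropna().to_numpy() for g in GROUPS]
    usable = [g for g in by_group if g.size >= 2]
    if len(usable) >= 2:
        kw = kruskal_wallis(usable)
        tests["kw_omega_groups"] = {"statistic": kw.statistic, "df": kw.df, "p": kw.p}
        if len(usable) >= 3:
            tests["dscf_omega_groups"] = dscf_posthoc(usable).tolist()

    # expression correlation (negative rho expected)
    expr = df.dropna(subset=["expression", "omega_m0"])
    if len(expr) >= 3:
        sp = spearman(expr["expression"].to_numpy(), expr["omega_m0"].to_numpy())
        tests["spearman_expression_omega"] = {"rho": sp.statistic, "p": sp.p}

    # per-state omegas across states (pooled) and across groups within states
    if {"omega_present", "omega_reduced", "omega_absent"} <= set(df.columns):
        sub = df.dropna(subset=["omega_present", "omega_reduced", "omega_absent"])
        if len(sub) >= 2:
            kw = kruskal_wallis(
                [sub["omega_present"], sub["omega_reduced"], sub["omega_absent"]]
            )
            tests["kw_omega_states"] = {"statistic": kw.statistic, "df": kw.df, "p": kw.p}
            patterns = sub["pattern_coarse"].value_counts().to_dict()
            fine = sub["pattern_fine"].value_counts().to_dict()
            tests["omega_pattern_counts"] = {"coarse": patterns, "fine": fine}
        if "p_branch" in df.columns and df["p_branch"].notna().sum() > 0:
            _contrast_chi2(df, "p_branch", config.alpha, tests, "branch")

    branch_site = {}
    relax = {}
    for contrast in config.contrasts:
        short = "pa" if contrast == "present-absent" else "pr"
        pcol = f"p_bs_{short}"
        if pcol in df.columns and df[pcol].notna().sum() > 0:
            _contrast_chi2(df, pcol, config.alpha, tests, f"branch_site_{short}")
            sig = df[df[pcol] < config.alpha]
            groups_w2 = [
                sig[sig.group == g][f"omega2_{short}"].dropna().to_numpy() for g in GROUPS
            ]
            usable = [g for g in groups_w2 if g.size >= 2]
            if len(usable) >= 2:
                kw = kruskal_wallis(usable)
                tests[f"kw_omega2_{short}"] = {"statistic": kw.statistic, "df": kw.df, "p": kw.p}
            strat_col = "n_losses" if contrast == "present-absent" else "n_reductions"
            strat = stratify_by_transitions(df.dropna(subset=[pcol]), config.min_transitions, strat_col)
            tests[f"branch_site_{short}_stratified_n"] = int(len(strat))
            cols = ["og_id", "group", pcol, f"q_bs_{short}", f"omega2_{short}",
                    f"n_sites_{short}", strat_col]
            branch_site[contrast] = df.dropna(subset=[pcol])[
                [c for c in cols if c in df.columns]
            ].copy()
        prcol = f"p_relax_{short}"
        if prcol in df.columns and df[prcol].notna().sum() > 0:
            _contrast_chi2(df, prcol, config.alpha, tests, f"relax_{short}")
            tested = df.dropna(subset=[prcol])
            sig = tested[tested[prcol] < config.alpha]
            for direction, name in ((">1", "intensified"), ("<1", "relaxed")):
                dsub = sig[sig[f"k_{short}"] > 1] if direction == ">1" else sig[sig[f"k_{short}"] < 1]
                counts = {
                    g: (int((dsub.group == g).sum()), int((tested.group == g).sum()))
                    for g in GROUPS
                }
                groups = [g for g in GROUPS if counts[g][1] > 0]
                observed = [counts[g][0] for g in groups]
                total = [counts[g][1] for g in groups]
                tests[f"relax_{short}_{name}_table"] = {
                    "groups": groups, "observed": observed, "total": total,
                }
                if sum(observed) > 0 and len(groups) >= 2:
                    res = chi_square_expected(
                        ContrastTable(groups, np.array(observed), np.array(total))
                    )
                    tests[f"relax_{short}_{name}_chi2"] = {
                        "statistic": res.statistic, "df": res.df, "p": res.p,
                    }
                kgroups = [dsub[dsub.group == g][f"k_{short}"].to_numpy() for g in GROUPS]
                usable = [g for g in kgroups if g.size >= 2]
                if len(usable) >= 2:
                    kw = kruskal_wallis(usable)
                    tests[f"kw_k_{short}_{name}"] = {
                        "statistic": kw.statistic, "df": kw.df, "p": kw.p,
                    }
            cols = ["og_id", "group", prcol, f"q_relax_{short}", f"k_{short}"]
            relax[contrast] = tested[[c for c in cols if c in df.columns]].copy()

    bias = df["codon_bias_absent"].dropna() if "codon_bias_absent" in df.columns else []
    if len(bias):
        tests["mean_codon_bias_absent"] = float(np.mean(bias))

    df_out = df.copy()
    for col in df_out.columns:
        if col.startswith("omega"):
            df_out[col] = df_out[col].clip(lower=0.01, upper=10.0)  # reporting caps
    df_out.to_csv(os.path.join(out_dir, "branch_models.tsv"), sep="\t", index=False)
    for contrast, frame in branch_site.items():
        frame.to_csv(
            os.path.join(out_dir, f"branch_site_{contrast}.tsv"), sep="\t", index=False
        )
    for contrast, frame in relax.items():
        frame.to_csv(os.path.join(out_dir, f"relax_{contrast}.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "stats_report.json"), "w") as fh:
        json.dump(tests, fh, indent=1, default=float)

    return StudyReport(
        branch=df, branch_site=branch_site, relax=relax, tests=tests,
        run_log=pd.DataFrame(), out_dir=out_dir,
    )
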