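"""End-to-end orchestration: generate -> build -> threshold -> metrics ->
compare -> couple -> clinical, with report tables and ground-truth recovery.

A single master seed drives every stage through a fixed spawn order of
`numpy.random.SeedSequence` children, so the whole run — including
permutation tests and null-model ensembles — is reproducible, and any
stage can be re-run in isolation with its own child seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectomes, crossmodal, graphnet, scn as scn_mod, stats, synth
from .core import (
    AFFILIATION_COLORS,
    CohortTable,
    ConnectivityMatrix,
    NodeScheme,
    default_node_scheme,
    write_cohort,
    write_matrix,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "demographic_table",
           "export_connectogram_edges", "read_connectogram_edges"]

# fixed spawn order of per-stage RNG streams off the master seed
_STAGES = ("cohort", "dti", "timeseries", "morphometry", "clinical",
           "metrics", "scn_perm")


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    SCN and FC networks are thresholded on positive edges only (their
    weights are signed correlations); DTI weights are nonnegative counts
    and use all nonzero edges.
    """

    generator: synth.GeneratorConfig = field(default_factory=synth.GeneratorConfig)
    rho: float = 0.05
    n_null: int = 100
    n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        gen = synth.GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)


@dataclass
class RunReport:
    """All report tables of one run plus the ground-truth recovery block."""

    demographics: pd.DataFrame  # Table-2 shape
    scn_global: pd.DataFrame  # Table-3 shape
    dti_global: pd.DataFrame  # Table-4 shape
    fc_global: pd.DataFrame  # Table-5 shape
    topology: pd.DataFrame  # Table-6 shape
    coupling: pd.DataFrame  # Table-7 shape
    coupling_comparison: dict
    clinical: pd.DataFrame  # Table-8 shape
    nodal: pd.DataFrame  # Table-9 shape
    recovery: dict
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in [
            ("table2_demographics", self.demographics),
            ("table3_scn_global", self.scn_global),
            ("table4_dti_global", self.dti_global),
            ("table5_fc_global", self.fc_global),
            ("table6_topology", self.topology),
            ("table7_coupling", self.coupling),
            ("table8_clinical", self.clinical),
            ("table9_nodal", self.nodal),
        ]:
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        with open(outdir / "coupling_comparison.json", "w") as f:
            json.dump(self.coupling_comparison, f, indent=2)
        with open(outdir / "ground_truth_recovery.json", "w") as f:
            json.dump(self.recovery, f, indent=2)
        with open(outdir / "run_log.json", "w") as f:
            json.dump(self.timings, f, indent=2)


def demographic_table(cohort: CohortTable) -> pd.DataFrame:
    """Group demographic/clinical summary with comparison statistics.

    Continuous variables use the Shapiro-gated t / Mann-Whitney policy;
    sex and handedness use Pearson's chi-square. Rounding follows the
    conventional table style: 1 decimal for means/SDs, 2 for p-values.
    """
    pat = cohort.patients
    ctl = cohort.controls
    if len(pat) == 0 or len(ctl) == 0:
        raise ValueError("both groups required for a demographic table")
    rows = []

    def cont_row(label, col, policy="auto"):
        c = stats.compare_groups(pat[col].to_numpy(float), ctl[col].to_numpy(float),
                                 policy=policy)
        rows.append({
            "characteristic": label,
            "patient": f"{c.mean_a:.1f} ± {c.sd_a:.1f}",
            "control": f"{c.mean_b:.1f} ± {c.sd_b:.1f}",
            "p": round(c.p, 2) if c.p >= 0.005 else "< 0.005",
            "test": c.test,
        })

    cont_row("Age (years)", "age")
    for label, col in (("Male/Female", "sex"), ("Handedness (R/L)", "handedness")):
        cats = ["M", "F"] if col == "sex" else ["R", "L"]
        ca = [int((pat[col] == k).sum()) for k in cats]
        cb = [int((ctl[col] == k).sum()) for k in cats]
        c = stats.chi_square_counts(ca, cb)
        rows.append({
            "characteristic": label,
            "patient": f"{ca[0]} / {ca[1]}",
            "control": f"{cb[0]} / {cb[1]}",
            "p": round(c.p, 2),
            "test": "chi_square",
        })
    a = pat["alsfrs_r"].to_numpy(float)
    rows.append({
        "characteristic": "ALSFRS-R",
        "patient": f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
        "control": "-",
        "p": "-",
        "test": "-",
    })
    cont_row("Dominant grip strength (kg)", "grip_right")
    cont_row("Non-dominant grip strength (kg)", "grip_left")
    return pd.DataFrame(rows)


def export_connectogram_edges(
    adjacency: np.ndarray, scheme: NodeScheme, path: str | Path
) -> Path:
    """Edge list of a thresholded network: source, target, weight, and the
    source node's affiliation colour class (one row per retained edge)."""
    path = Path(path)
    names = scheme.names
    aff = scheme.affiliation
    i, j = np.nonzero(np.triu(adjacency, 1))
    with open(path, "w") as f:
        f.write("source\ttarget\tweight\taffiliation\tcolor\n")
        for a, b in zip(i, j):
            f.write(
                f"{names[a]}\t{names[b]}\t{adjacency[a, b]:.12g}\t"
                f"{aff[a]}\t{AFFILIATION_COLORS[aff[a]]}\n"
            )
    return path


def read_connectogram_edges(path: str | Path, scheme: NodeScheme) -> np.ndarray:
    """Rebuild the adjacency matrix from an exported edge list."""
    df = pd.read_csv(path, sep="\t")
    n = len(scheme)
    adj = np.zeros((n, n))
    si = scheme.indices_of(df["source"].tolist())
    ti = scheme.indices_of(df["target"].tolist())
    adj[si, ti] = df["weight"].to_numpy(float)
    return adj + adj.T


def _group_mean(mats: list[ConnectivityMatrix], modality: str, scheme) -> ConnectivityMatrix:
    stack = np.mean([m.values for m in mats], axis=0)
    return ConnectivityMatrix.create(stack, scheme, modality=modality, level="group",
                                     weight_kind=mats[0].weight_kind)


def _metric_rows(
    label: str,
    suites_a: list[graphnet.GraphMetrics],
    suites_b: list[graphnet.GraphMetrics],
    metric_keys: list[tuple[str, str]],
) -> pd.DataFrame:
    """Mann-Whitney comparison of per-subject global metrics, BH-FDR
    adjusted across the rows of one table block."""
    rows = []
    raw_p = []

    def values(suites, key):
        v = np.array([np.nan if s.global_dict()[key] is None else s.global_dict()[key]
                      for s in suites], float)
        return v[np.isfinite(v)]

    for key, pretty in metric_keys:
        va = values(suites_a, key)
        vb = values(suites_b, key)
        if len(va) < 3 or len(vb) < 3 or np.ptp(np.concatenate([va, vb])) == 0:
            u, p, r_rb = len(va) * len(vb) / 2.0, 1.0, 0.0
        else:
            c = stats.compare_groups(va, vb, policy="mann_whitney")
            u, p, r_rb = c.statistic, c.p, c.effect_size
        rows.append({
            "block": label, "metric": pretty,
            "patient": f"{va.mean():.3f} ± {va.std(ddof=1):.3f}",
            "control": f"{vb.mean():.3f} ± {vb.std(ddof=1):.3f}",
            "U": u, "p": round(p, 3), "effect_size_r": round(abs(r_rb), 2),
        })
        raw_p.append(p)
    _, p_adj = stats.fdr_bh(raw_p)
    for row, pa in zip(rows, p_adj):
        row["p_fdr"] = round(float(pa), 3)
    return pd.DataFrame(rows)


GLOBAL_KEYS = [
    ("mean_strength", "Mean connection strength"),
    ("global_efficiency", "Global efficiency"),
    ("mean_degree", "Mean nodal degree"),
    ("clustering", "Clustering coefficient"),
]
TOPOLOGY_KEYS = [
    ("path_length", "Path length (L)"),
    ("assortativity", "Assortativity (r)"),
    ("sigma", "Small-worldness (sigma)"),
    ("rich_club_phi_norm", "Rich-club (phi)"),
]
NODAL_REGIONS = ["L_precentral", "R_precentral", "L_postcentral", "R_postcentral"]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full synthetic-cohort pipeline and assemble the report.

    Stages: cohort generation; per-subject structural connectomes and
    rest/task time series; task regression; FC construction; per-subject
    fixed-density graph metrics with degree-preserving nulls; group-level
    SCNs with permutation inference; cross-modal coupling and its Fisher
    comparison; planted clinical correlations; ground-truth recovery.
    """
    t0 = time.time()
    timings: dict[str, float] = {}
    gen = config.generator
    scheme = default_node_scheme()
    rngs = stage_rngs(config.seed)

    cohort = synth.generate_subjects(gen, rngs["cohort"])
    df = cohort.rows
    timings["cohort"] = time.time() - t0

    # per-subject structural and functional matrices
    t = time.time()
    dti: dict[str, ConnectivityMatrix] = {}
    fc_rest: dict[str, ConnectivityMatrix] = {}
    fc_task: dict[str, ConnectivityMatrix] = {}
    design = connectomes.TaskDesign(total_volumes=gen.t_task, tr=gen.tr_seconds,
                                    block_seconds=gen.block_seconds)
    regs = connectomes.task_regressors(design)
    for _, row in df.iterrows():
        sid, group = row["subject_id"], row["group"]
        m = synth.generate_structural_connectome(scheme, gen, group, rngs["dti"], sid)
        dti[sid] = m
        x_rest = synth.generate_timeseries(m, gen, "rest", rngs["timeseries"])
        ts_rest = connectomes.RoiTimeseries(x_rest, scheme, tr=gen.tr_seconds,
                                            condition="rest", subject_id=sid)
        fc_rest[sid] = connectomes.fc_from_timeseries(ts_rest)
        x_task = synth.generate_timeseries(m, gen, "task", rngs["timeseries"])
        ts_task = connectomes.RoiTimeseries(x_task, scheme, tr=gen.tr_seconds,
                                            condition="task", subject_id=sid)
        fc_task[sid] = connectomes.fc_from_timeseries(connectomes.regress_task(ts_task, regs))
    timings["matrices"] = time.time() - t

    # per-subject graph metric suites
    t = time.time()
    null_cfg = graphnet.NullConfig(n_null=config.n_null)
    thr_pos = graphnet.ThresholdConfig(config.rho, positive_only=True)
    thr_dti = graphnet.ThresholdConfig(config.rho, positive_only=False)
    suites: dict[str, dict[str, graphnet.GraphMetrics]] = {"DTI": {}, "FC_rest": {}, "FC_task": {}}
    for sid in df["subject_id"]:
        suites["DTI"][sid] = graphnet.metrics_suite(dti[sid], thr_dti, null_cfg, rngs["metrics"])
        suites["FC_rest"][sid] = graphnet.metrics_suite(fc_rest[sid], thr_pos, null_cfg, rngs["metrics"])
        suites["FC_task"][sid] = graphnet.metrics_suite(fc_task[sid], thr_pos, null_cfg, rngs["metrics"])
    timings["metrics"] = time.time() - t

    # plant the clinical association on structural global efficiency
    eglob = pd.Series(
        {sid: suites["DTI"][sid].global_efficiency for sid in df["subject_id"]}
    )
    cohort = synth.plant_clinical_link(cohort, eglob, gen.clinical_rho, rngs["clinical"])
    df = cohort.rows

    # morphometry -> SCN
    t = time.time()
    morph = synth.generate_morphometry(cohort, scheme, gen, rngs["morphometry"])
    adjusted = scn_mod.residualize_covariates(morph)
    pat_ids = df.loc[df["group"] == "patient", "subject_id"].tolist()
    ctl_ids = df.loc[df["group"] == "control", "subject_id"].tolist()
    scn_pat = scn_mod.build_scn(adjusted, pat_ids, "patient")
    scn_ctl = scn_mod.build_scn(adjusted, ctl_ids, "control")
    scn_cmp = scn_mod.scn_group_compare(
        adjusted, pat_ids, ctl_ids, list(scn_mod.SCN_METRICS),
        n_perm=config.n_perm, rng=rngs["scn_perm"], rho=config.rho,
    )
    mp = scn_mod.scn_metrics(scn_pat, config.rho)
    mc = scn_mod.scn_metrics(scn_ctl, config.rho)
    scn_table = pd.DataFrame([
        {"metric": name, "patient": round(mp[name], 3), "control": round(mc[name], 3),
         "p_uncorrected": round(scn_cmp[name]["p"], 3)}
        for name in scn_mod.SCN_METRICS
    ])
    timings["scn"] = time.time() - t

    # group-level matrices and cross-modal coupling
    t = time.time()
    group_mats: dict[tuple[str, str], ConnectivityMatrix] = {}
    for modality, store in (("DTI", dti), ("FC_rest", fc_rest), ("FC_task", fc_task)):
        for group, ids in (("patient", pat_ids), ("control", ctl_ids)):
            group_mats[(modality, group)] = _group_mean(
                [store[s] for s in ids], modality, scheme)
    group_mats[("SCN", "patient")] = scn_pat.to_connectivity(scheme)
    group_mats[("SCN", "control")] = scn_ctl.to_connectivity(scheme)

    pairs = [("SCN", "DTI"), ("SCN", "FC_rest"), ("SCN", "FC_task"),
             ("DTI", "FC_rest"), ("DTI", "FC_task")]
    coupling_rows = []
    couplings: dict[tuple[str, str, str], crossmodal.CouplingResult] = {}
    for ma, mb in pairs:
        for group in ("patient", "control"):
            c = crossmodal.coupling(group_mats[(ma, group)], group_mats[(mb, group)])
            couplings[(ma, mb, group)] = c
            coupling_rows.append({
                "matrix_pair": f"{ma} vs {mb}", "group": group,
                "r": round(c.r, 3), "p": c.p, "n_edges": c.n_edges,
            })
    coupling_table = pd.DataFrame(coupling_rows)
    ct = couplings[("DTI", "FC_task", "patient")]
    cc = couplings[("DTI", "FC_task", "control")]
    comp = crossmodal.fisher_compare(ct.r, ct.n_edges, cc.r, cc.n_edges)
    coupling_comparison = {
        "contrast": "DTI-FC_task coupling, patient vs control",
        "z": comp.z, "p": comp.p,
        "r_patient": ct.r, "r_control": cc.r, "n_edges": ct.n_edges,
    }
    timings["coupling"] = time.time() - t

    # group tables
    demographics = demographic_table(cohort)
    dti_table = _metric_rows(
        "Structural connectivity (DTI)",
        [suites["DTI"][s] for s in pat_ids], [suites["DTI"][s] for s in ctl_ids],
        GLOBAL_KEYS)
    fc_blocks = []
    for modality, label in (("FC_rest", "Resting-state fMRI"),
                            ("FC_task", "Task-based fMRI")):
        fc_blocks.append(_metric_rows(
            label,
            [suites[modality][s] for s in pat_ids],
            [suites[modality][s] for s in ctl_ids],
            GLOBAL_KEYS))
    fc_table = pd.concat(fc_blocks, ignore_index=True)
    topo_blocks = []
    for modality, label in (("DTI", "Structural connectivity (DTI)"),
                            ("FC_rest", "Functional connectivity (Rest)"),
                            ("FC_task", "Functional connectivity (Task)")):
        keys = TOPOLOGY_KEYS if config.n_null > 0 else TOPOLOGY_KEYS[:2]
        topo_blocks.append(_metric_rows(
            label,
            [suites[modality][s] for s in pat_ids],
            [suites[modality][s] for s in ctl_ids],
            keys))
    topology = pd.concat(topo_blocks, ignore_index=True)

    # nodal metrics for key motor regions
    nodal_rows = []
    region_idx = scheme.indices_of(NODAL_REGIONS)
    for name, idx in zip(NODAL_REGIONS, region_idx):
        for modality, metric, attr in (("DTI", "Degree", "degree"),
                                       ("FC_rest", "Strength", "strength")):
            va = np.array([getattr(suites[modality][s], attr)[idx] for s in pat_ids])
            vb = np.array([getattr(suites[modality][s], attr)[idx] for s in ctl_ids])
            if np.ptp(np.concatenate([va, vb])) == 0:
                p = 1.0
            else:
                p = stats.compare_groups(va, vb, policy="mann_whitney").p
            nodal_rows.append({
                "node": name, "metric": f"{metric} ({modality})",
                "patient": f"{va.mean():.2f} ± {va.std(ddof=1):.2f}",
                "control": f"{vb.mean():.2f} ± {vb.std(ddof=1):.2f}",
                "p": round(p, 3),
            })
    nodal = pd.DataFrame(nodal_rows)

    # clinical correlations (planted on structural global efficiency)
    metrics_by_subject = pd.DataFrame({
        "structural_global_efficiency": eglob,
        "structural_clustering": pd.Series(
            {sid: suites["DTI"][sid].clustering for sid in df["subject_id"]}),
        "functional_mean_strength": pd.Series(
            {sid: suites["FC_rest"][sid].mean_strength for sid in df["subject_id"]}),
    })
    clin = stats.clinical_correlation_table(metrics_by_subject, cohort, [
        ("structural_global_efficiency", "grip_left"),
        ("structural_clustering", "grip_left"),
        ("structural_clustering", "alsfrs_r"),
        ("structural_global_efficiency", "alsfrs_r"),
        ("functional_mean_strength", "alsfrs_r"),
    ])
    clinical = pd.DataFrame([
        {"network_metric": c.metric, "clinical_measure": c.clinical,
         "spearman_rho": round(c.rho, 2), "p": round(c.p, 3), "stars": c.stars, "n": c.n}
        for c in clin
    ])

    # ground-truth recovery block
    t = time.time()
    per_subj_coupling = [
        crossmodal.coupling(dti[s], fc_rest[s]).r for s in df["subject_id"]
    ]
    mask = synth._deficit_mask(scheme)
    iu = np.triu_indices(len(scheme), 1)
    motor_mask = mask[iu]

    def inter_motor_strength(sid):
        return float(dti[sid].values[iu][motor_mask].mean())

    sa = [inter_motor_strength(s) for s in pat_ids]
    sb = [inter_motor_strength(s) for s in ctl_ids]
    deficit_cmp = stats.compare_groups(sa, sb, policy="mann_whitney")
    planted_clin = clin[0]
    recovery = {
        "planted_rho_sf": gen.coupling_rho_sf,
        "recovered_rho_sf_mean": float(np.mean(per_subj_coupling)),
        "planted_delta": gen.interhemispheric_deficit,
        "interhemispheric_motor_diff": float(np.mean(sa) - np.mean(sb)),
        "interhemispheric_motor_p": deficit_cmp.p,
        "planted_clinical_rho": gen.clinical_rho,
        "recovered_clinical_rho": planted_clin.rho,
    }
    timings["recovery"] = time.time() - t
    timings["total"] = time.time() - t0

    report = RunReport(
        demographics=demographics, scn_global=scn_table, dti_global=dti_table,
        fc_global=fc_table, topology=topology, coupling=coupling_table,
        coupling_comparison=coupling_comparison, clinical=clinical, nodal=nodal,
        recovery=recovery, timings=timings,
    )
    if outdir is not None:
        outdir = Path(outdir)
        report.write(outdir)
        write_cohort(cohort, outdir / "cohort.tsv")
        edges_dir = outdir / "edges"
        edges_dir.mkdir(exist_ok=True)
        for (modality, group), mat in group_mats.items():
            cfg = thr_dti if modality == "DTI" else thr_pos
            wadj = graphnet.proportional_threshold(
                mat, graphnet.ThresholdConfig(cfg.rho, cfg.positive_only, "weighted"))
            export_connectogram_edges(wadj, scheme, edges_dir / f"{modality}_{group}.tsv")
            write_matrix(mat, outdir / f"{modality}_{group}.tsv")
        with open(outdir / "ground_truth.json", "w") as f:
            json.dump(
                synth.GroundTruth(
                    delta=gen.interhemispheric_deficit,
                    rho_sf=gen.coupling_rho_sf,
                    clinical_rho=gen.clinical_rho,
                    module_partition={k: [int(i) for i in v]
                                      for k, v in synth.module_partition(scheme).items()},
                    seed=config.seed,
                ).to_dict(), f, indent=2)
    return report
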