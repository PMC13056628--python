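#!/usr/bin/env python
"""Step 1 — simulate the multimodal cohort.

Generates the two-group cohort (15 patients / 14 controls), regional
morphometry with age/sex/TIV effects, per-subject structural connectomes
with the planted interhemispheric motor/premotor deficit, and rest/task
functional matrices coupled to structure at the planted rho_sf. Small
tables land in results/synthetic/; the per-subject matrices (bulky) go to
scratch/sim/.

Run:  python analysis/01_simulate.py [--seed 0]
"""

import argparse
import json
from pathlib import Path

from mmconn import synth, connectomes
from mmconn.core import default_node_scheme, write_cohort, write_matrix
from mmconn.pipeline import RunConfig, stage_rngs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed)
    gen = cfg.generator
    scheme = default_node_scheme()
    rngs = stage_rngs(cfg.seed)
    out = ROOT / "results" / "synthetic"
    sim = ROOT / "scratch" / "sim"
    out.mkdir(parents=True, exist_ok=True)
    sim.mkdir(parents=True, exist_ok=True)

    cohort = synth.generate_subjects(gen, rngs["cohort"])
    write_cohort(cohort, out / "cohort.tsv")

    morph = synth.generate_morphometry(cohort, scheme, gen, rngs["morphometry"])
    morph.values.to_csv(out / "morphometry.tsv", sep="\t")
    morph.covariates.to_csv(out / "covariates.tsv", sep="\t")

    design = connectomes.TaskDesign(total_volumes=gen.t_task, tr=gen.tr_seconds,
                                    block_seconds=gen.block_seconds)
    regs = connectomes.task_regressors(design)
    for _, row in cohort.rows.iterrows():
        sid, group = row["subject_id"], row["group"]
        m = synth.generate_structural_connectome(scheme, gen, group, rngs["dti"], sid)
        write_matrix(m, sim / f"dti_{sid}.tsv")
        for condition, t in (("rest", gen.t_rest), ("task", gen.t_task)):
            x = synth.generate_timeseries(m, gen, condition, rngs["timeseries"])
            ts = connectomes.RoiTimeseries(x, scheme, tr=gen.tr_seconds,
                                           condition=condition, subject_id=sid)
            if condition == "task":
                ts = connectomes.regress_task(ts, regs)
            fc = connectomes.fc_from_timeseries(ts)
            write_matrix(fc, sim / f"fc_{condition}_{sid}.tsv")

    truth = synth.GroundTruth(
        delta=gen.interhemispheric_deficit, rho_sf=gen.coupling_rho_sf,
        clinical_rho=gen.clinical_rho,
        module_partition={k: [int(i) for i in v]
                          for k, v in synth.module_partition(scheme).items()},
        seed=cfg.seed)
    (out / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=2))

    n_pat, n_ctl = len(cohort.patients), len(cohort.controls)
    print(f"simulated {n_pat} patients / {n_ctl} controls (seed {cfg.seed})")
    print(f"planted: delta={gen.interhemispheric_deficit}, rho_sf={gen.coupling_rho_sf}, "
          f"clinical_rho={gen.clinical_rho}")
    print(f"cohort + morphometry -> {out}; matrices -> {sim}")


if __name__ == "__main__":
    main()
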