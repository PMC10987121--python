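"""Generate the synthetic study cohorts.

Emits, under results/sim/:
  * a cross-sectional cohort of TRD repertoires whose clone-size skew rises
    along the group gradient HC -> miPTC -> wiPTC -> PDTC -> ATC (Zipf
    exponents 0.5, 0.8, 1.1, 1.5, 2.0; three subjects per group),
  * a sharing cohort with a common public clonotype pool, and
  * a six-timepoint longitudinal series under the baseline/TKI/radio/PD-1
    schedule, with planted clone labels.

All downstream drivers read these tables back through the package's IO.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gdrep import (
    LongitudinalSimConfig,
    SimConfig,
    simulate_cohort,
    simulate_longitudinal,
    simulate_repertoire,
    write_clonotype_table,
)

GROUP_EXPONENTS = {"HC": 0.5, "miPTC": 0.8, "wiPTC": 1.1, "PDTC": 1.5, "ATC": 2.0}
SUBJECTS_PER_GROUP = 3


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", default="results/sim")
    ap.add_argument("--n-clones", type=int, default=2000)
    ap.add_argument("--reads", type=int, default=100_000)
    args = ap.parse_args()
    out = Path(args.out_dir)
    (out / "cross_sectional").mkdir(parents=True, exist_ok=True)
    (out / "sharing").mkdir(exist_ok=True)
    (out / "longitudinal").mkdir(exist_ok=True)

    meta_rows = []
    seed = args.seed
    for group, s in GROUP_EXPONENTS.items():
        for k in range(SUBJECTS_PER_GROUP):
            seed += 1
            sample_id = f"{group}-{k + 1:02d}"
            cfg = SimConfig(n_clones=args.n_clones, zipf_exponent=s,
                            total_reads=args.reads, seed=seed)
            rep, truth = simulate_repertoire(cfg, sample_id=sample_id,
                                             subject_id=sample_id, group=group)
            write_clonotype_table(rep, out / "cross_sectional" / f"{sample_id}.tsv")
            meta_rows.append({"sample_id": sample_id, "subject_id": sample_id,
                              "group": group, "zipf_exponent": s, "seed": seed})
    pd.DataFrame(meta_rows).to_csv(out / "cross_sectional" / "metadata.tsv",
                                   sep="\t", index=False)
    print(f"cross-sectional: {len(meta_rows)} samples, "
          f"{args.n_clones} clones x {args.reads} reads each")

    share_cfg = SimConfig(n_clones=args.n_clones, zipf_exponent=1.0,
                          total_reads=args.reads, seed=args.seed + 1000)
    reps, truth = simulate_cohort(share_cfg, n_subjects=6,
                                  public_pool_size=2 * args.n_clones,
                                  public_fraction=0.2)
    for rep in reps:
        write_clonotype_table(rep, out / "sharing" / f"{rep.sample_id}.tsv")
    truth.to_csv(out / "sharing" / "ground_truth.tsv", sep="\t", index=False)
    print(f"sharing cohort: 6 subjects, public fraction 0.2")

    lcfg = LongitudinalSimConfig(
        base=SimConfig(n_clones=args.n_clones // 2, zipf_exponent=1.0,
                       total_reads=args.reads, seed=args.seed + 2000)
    )
    lreps, ltruth = simulate_longitudinal(lcfg)
    for tp, rep in lreps.items():
        write_clonotype_table(rep, out / "longitudinal" / f"{tp}.tsv")
    ltruth.to_csv(out / "longitudinal" / "ground_truth.tsv", sep="\t", index=False)
    schedule = [{"sample_id": rep.sample_id, "subject_id": rep.subject_id,
                 "timepoint": tp, "phase": lcfg.schedule.phases[tp]}
                for tp, rep in lreps.items()]
    pd.DataFrame(schedule).to_csv(out / "longitudinal" / "schedule.tsv",
                                  sep="\t", index=False)
    print(f"longitudinal: {len(lreps)} timepoints, "
          f"planted labels: {ltruth.label.value_counts().to_dict()}")

    (out / "config.json").write_text(json.dumps(
        {"seed": args.seed, "n_clones": args.n_clones, "reads": args.reads,
         "group_exponents": GROUP_EXPONENTS}, indent=2))


if __name__ == "__main__":
    main()
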