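"""Generate the synthetic analysis cohorts.

The original discovery microarray data are not deposited, so the pipeline
runs on synthetic stand-ins with the same statistical structure: a
19-vs-11 two-class log-expression cohort (2000 genes, 5 planted markers at
3 SD), a matching signal-free null cohort, a risk-score-driven survival
cohort, and duplicate-core immunostaining scores (group means 2.1 vs 2.6).
Ground truth goes to sidecar files, never into the analysis inputs.
"""

import argparse
from pathlib import Path

import nacsig as ns
from nacsig.rgife import derive_seed
from nacsig.simulate import write_ground_truth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/synthetic", type=Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    disc = ns.generate_two_group_cohort(
        ns.SimulationSpec(19, 11, 2000, 5, 3.0, seed=derive_seed(args.seed, 1)))
    disc.write(args.out / "discovery_expression.tsv", args.out / "discovery_labels.tsv")
    write_ground_truth(disc, args.out / "discovery_truth.json")

    null = ns.generate_null_cohort(
        ns.SimulationSpec(19, 11, 2000, 0, seed=derive_seed(args.seed, 2)))
    null.write(args.out / "null_expression.tsv", args.out / "null_labels.tsv")

    sexpr, surv = ns.generate_survival_cohort(
        ns.SurvivalSimSpec(400, (1.0, -0.5, 0.0), 0.1, 0.025,
                           seed=derive_seed(args.seed, 3)))
    sexpr.write(args.out / "survival_expression.tsv", args.out / "survival_labels.tsv")
    surv.write(args.out / "survival_clinical.tsv")

    ihc = ns.generate_ihc_cohort(ns.IHCSimSpec(seed=derive_seed(args.seed, 4)))
    ihc.write(args.out / "ihc_scores.tsv")

    print(f"Discovery cohort: {disc.n_genes} genes x {disc.n_samples} samples, "
          f"planted markers: {', '.join(disc.informative_genes)}")
    print(f"Null cohort, survival cohort (n={surv.n_samples}, "
          f"{int(surv.event.sum())} events) and IHC scores written to {args.out}")


if __name__ == "__main__":
    main()
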