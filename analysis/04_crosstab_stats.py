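#!/usr/bin/env python
"""Cross-classification statistics: the 3x4 contingency table with
chi-square + adjusted-residual analysis, per-patient detection rates with
Fisher comparisons, and within-patient heterogeneity — on the simulated
cohort and on the published 59-cell cross-tab.

Reads results/annotations.tsv and results/synthetic/clinical.csv; writes
results/{crosstab,residuals,detection}.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ctcpheno import crosstab as ct, io, reference
from ctcpheno.core import CellAnnotation


def load_annotations(path: Path):
    df = pd.read_csv(path, sep="\t")
    annotations = [
        CellAnnotation(
            cell_id=str(r.cell_id), patient_id=str(r.patient_id),
            is_cluster=bool(r.is_cluster),
            epithelial_score=float(r.epithelial_score),
            stem_score=float(r.stem_score), emt_score=float(r.emt_score),
            epithelial_group=r.epithelial_group,
            emt_stem_group=r.emt_stem_group)
        for r in df.itertuples()
    ]
    return ct.assign_categories(annotations)


def report(tag, annotations, clinical):
    table = ct.cross_tabulate(annotations)
    chi = ct.chi_square_test(table)
    residuals = ct.adjusted_residuals(table)
    print(f"[{tag}] n={table.n}; chi-square {chi['statistic']:.1f} "
          f"(df={chi['df']}, p={chi['p']:.2e}); "
          f"{ct.count_significant(residuals, 'high', 0.05)} categories "
          f"enriched, {ct.count_significant(residuals, 'low', 0.05)} depleted")
    detection = ct.patient_positivity(annotations, clinical)
    rates = {t: f"{detection.rate_pct(t)}%" for t in detection.positive}
    print(f"[{tag}] detection rates: {rates}")
    p = ct.fisher_exact_2x2(
        [[detection.positive["epithelial"], detection.negative("epithelial")],
         [detection.positive["emt"], detection.negative("emt")]])
    print(f"[{tag}] Fisher, epithelial vs EMT detection: p = {p:.4g}")
    het = ct.heterogeneity_summary(annotations)
    print(f"[{tag}] patients with >=2 CTC categories: "
          f"{het['n_multi_category']}")
    return table, residuals, detection


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    annotations = load_annotations(args.out_dir / "annotations.tsv")
    clinical = io.read_clinical_table(
        args.out_dir / "synthetic" / "clinical.csv")
    table, residuals, detection = report("synthetic", annotations, clinical)
    io.write_table(table.to_frame(), args.out_dir / "crosstab.tsv",
                   index=True)
    io.write_table(ct.residual_table(residuals),
                   args.out_dir / "residuals.tsv")
    io.write_table(detection.to_frame(), args.out_dir / "detection.tsv")

    ref_annotations = ct.assign_categories(reference.crosstab_annotations())
    ref_table = ct.cross_tabulate(ref_annotations)
    ref_res = ct.adjusted_residuals(ref_table)
    chi = ct.chi_square_test(ref_table)
    print(f"[published 59-cell table] chi-square {chi['statistic']:.1f} "
          f"(p={chi['p']:.1e}); "
          f"{ct.count_significant(ref_res, 'high', 0.05)} enriched / "
          f"{ct.count_significant(ref_res, 'low', 0.05)} depleted categories")
    det_ann, det_clin = reference.detection_fixture()
    det = ct.patient_positivity(det_ann, det_clin)
    print("[published detection] "
          + ", ".join(f"{t}: {det.rate_pct(t)}%" for t in det.positive))


if __name__ == "__main__":
    main()
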