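"""The final PK-marker screen.

Combines four criteria per analyte: favorable PK (terminal phase estimable
at the medium dose or below, from the published detection pattern),
representativeness (per-parameter t-tests of the analyte's per-subject NCA
against the effect-weighted integrated PK of the simulated cohort),
disease-relevance annotation, and validated cardiomyocyte protection.
Prints the criterion sets, the Venn regions and the marker call.
"""

import argparse
from pathlib import Path

import pandas as pd

from pkmarker.integration import effect_weights, integrate_cohort, integrated_dose
from pkmarker.io import read_pk_table
from pkmarker.nca import compute_nca, nca_table
from pkmarker.published import (
    CVD_RELEVANT,
    DETECTION_PATTERN,
    EFFECT_AUC_PCT_UM,
    EFFECT_VALIDATED,
)
from pkmarker.screening import (
    CriterionFlags,
    favorable_pk,
    representativeness_test,
    screen_markers,
)
from pkmarker.simulate import default_study_design

ANALYTES = ("HSYA", "SYR", "p-CA", "SCU", "p-HBA", "RU")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    profiles = read_pk_table(args.outdir / "pk_concentrations.csv")
    contents = {a.name: a.content for a in default_study_design().analytes}
    per_subject = pd.read_csv(args.outdir / "nca_per_subject.csv")

    favorable = favorable_pk(DETECTION_PATTERN)
    print(f"favorable PK: {sorted(favorable)}")

    # effect-weighted integrated PK over the two protective ingredients
    w = effect_weights(EFFECT_AUC_PCT_UM)
    two = [p for p in profiles if p.analyte in w.omegas]
    integ = integrate_cohort(two, w)
    integ_results = []
    for p in integ:
        orig = [q for q in two if q.subject_id == p.subject_id]
        d = integrated_dose(w, {q.analyte: contents[q.analyte] * q.volume_dose
                                for q in orig})
        integ_results.append(compute_nca(p, d))
    integ_tbl = nca_table(integ_results)

    flags, rep_rows = [], []
    for a in ANALYTES:
        representative = False
        if a in favorable:
            cand = per_subject[per_subject["analyte"] == a]
            rep = representativeness_test(cand, integ_tbl)
            representative = rep.representative
            t = rep.table.assign(analyte=a)
            rep_rows.append(t)
            n_sig = int(t["significant"].sum())
            print(f"representativeness {a}: {'yes' if representative else 'no'} "
                  f"({n_sig} significant parameter cells)")
        flags.append(
            CriterionFlags(a, a in favorable, representative,
                           a in CVD_RELEVANT, a in EFFECT_VALIDATED)
        )

    pd.concat(rep_rows).to_csv(args.outdir / "representativeness.csv", index=False)
    report = screen_markers(flags)
    pd.DataFrame(
        [(f.analyte, f.favorable_pk, f.representative, f.cvd_relevant,
          f.effect_validated, f.analyte in report.markers) for f in flags],
        columns=["analyte", "favorable_pk", "representative", "cvd_relevant",
                 "effect_validated", "marker"],
    ).to_csv(args.outdir / "marker_screen.csv", index=False)

    print("criterion sets:")
    for c, s in report.criterion_sets.items():
        print(f"  {c:<18s}: {sorted(s)}")
    print("Venn regions (criteria satisfied -> analytes):")
    for key, members in sorted(report.venn_regions().items(), key=lambda kv: -len(kv[0])):
        print(f"  {len(key)}/4 {sorted(key)}: {sorted(members)}")
    print(f"PK marker(s): {sorted(report.markers) or 'none'}")


if __name__ == "__main__":
    main()
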