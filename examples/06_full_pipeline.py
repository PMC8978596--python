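"""The whole pipeline in one call, writing report files to disk.

Equivalent to the shell command:
    evprofiler run --manifest cohort.tsv --mode change --out out/
"""

import json
import tempfile

import evprofiler as ev

cohort = ev.generate_cohort(ev.CohortSpec(events_min=2000, events_max=4000),
                            seed=6)

with tempfile.TemporaryDirectory() as outdir:
    config = ev.PipelineConfig(mode="change", outdir=outdir, seed=6)
    report = ev.run_pipeline(cohort.manifest, config, tables=cohort.tables,
                             biomarkers=cohort.biomarkers, nta=cohort.nta)
    analysis = report["analyses"]["change"]
    print(f"candidates ({analysis['n_candidates']}):")
    for c in analysis["comparisons"]:
        flag = "*" if c["p"] < config.alpha else " "
        print(f" {flag} {c['variable']}: {c['test']}, p = {c['p']:.4f}")
    print("\nROC of significant candidates:")
    for r in analysis["roc"]:
        print(f"   {r['variable']}: AUC = {r['auc']:.2f}, "
              f"rule {r['direction']} {r['cutoff']:.2f}")
    print("\npaired stress effects (all subjects, D0 -> D3):")
    for name, res in report["stress_effects"].items():
        print(f"   {name}: {res['test']}, p = {res['p']:.4f}")
    with open(f"{outdir}/report.json") as fh:
        print(f"\nreport.json keys: {sorted(json.load(fh))}")
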