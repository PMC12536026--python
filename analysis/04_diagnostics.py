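"""Diagnostic modelling on the simulated cohort.

Per-marker ROC curves with DeLong confidence intervals and Youden
cut-offs, the combined three-marker logistic nomogram, its bootstrap
optimism-corrected calibration (1,000 resamples), and the decision
curve of its net clinical benefit.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import CONFIG, RUN_DIR, ensure_simulated, publish  # noqa: E402

from glympipe.pipeline import stage_diagnostics  # noqa: E402


def main() -> None:
    ensure_simulated()
    table = pd.read_csv(RUN_DIR / "subject_table_markers.csv"
                        if (RUN_DIR / "subject_table_markers.csv").exists()
                        else RUN_DIR / "subject_table.csv")
    res = stage_diagnostics(table, CONFIG, RUN_DIR)
    publish("roc_summary.json", "model.json", "calibration.csv", "dca.csv",
            "roc_coupling_index.csv", "roc_alps_index.csv",
            "roc_cpv_fraction_pct.csv")

    roc = json.loads((RUN_DIR / "roc_summary.json").read_text())
    print("per-marker and combined discrimination (ALS vs HC):")
    for name, r in roc.items():
        print(f"  {name}: AUC = {r['auc']:.3f} "
              f"(95% CI {r['ci95'][0]:.3f}-{r['ci95'][1]:.3f}), "
              f"cutoff = {r['cutoff']:.3g}, sens = {r['sensitivity']:.3f}, "
              f"spec = {r['specificity']:.3f}")

    cal = res["calibration"].dropna(subset=["observed_corrected"])
    max_dev = (cal["observed_corrected"] - cal["mean_predicted"]).abs().max()
    print(f"calibration ({CONFIG.n_boot} bootstrap refits): max "
          f"|corrected observed - predicted| across bins = {max_dev:.3f}")

    dca = res["dca"]
    better = dca[(dca["net_benefit_model"] > dca["net_benefit_all"])
                 & (dca["net_benefit_model"] > 0)]
    if len(better):
        print(f"decision curve: model beats treat-all/none for thresholds "
              f">= {better['threshold'].min():.2f}")


if __name__ == "__main__":
    main()
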