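"""Fit the per-species ensemble niche models and project both periods.

For each species: presence + pseudo-absence training sets (prevalence 0.5,
ten repetitions, 2-cell buffer; real absences for trees), a four-family
committee evaluated by holdout AUC, an AUC-weighted consensus projected
under reference and future climates, and a max-TSS binarization applied
identically to both periods.
"""

import importlib

import pandas as pd

cfg = importlib.import_module("00_config")

from nicheshift.pipeline import stage_model  # noqa: E402


def main() -> None:
    info = stage_model(cfg.CONFIG, cfg.RUN_DIR)
    print(f"modelled {info['n_modelled']} species; "
          f"{len(info['skipped'])} skipped:")
    for sid, reason in sorted(info["skipped"].items()):
        print(f"  {sid}: {reason}")
    report = pd.read_csv(cfg.RUN_DIR / "model_report.csv")
    print(f"member models fitted: {len(report)}; "
          f"median holdout AUC {report['auc'].median():.3f} "
          f"(floor {cfg.CONFIG.auc_floor} for consensus membership)")


if __name__ == "__main__":
    main()
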