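"""Compute the climate-change impact statistics over the network.

Per protected area: species gain G, loss L, relative gain rG and loss rL,
turnover T, richness per period and representativity at three nested
scales. Per species: the change in protected range dPR. Distributions are
reported both over protected areas and over protected land, and richness /
representativity are compared across periods with Wilcoxon signed-rank
tests. The small summary tables are copied into results/.
"""

import importlib
import json
import shutil

cfg = importlib.import_module("00_config")

from nicheshift.pipeline import stage_metrics  # noqa: E402


def main() -> None:
    summary = stage_metrics(cfg.CONFIG, cfg.RUN_DIR)

    rich = summary["richness_test"]
    print("richness, reference vs future (Wilcoxon signed-rank): "
          f"V = {rich['statistic']:.1f}, p = {rich['p_value']:.2e}, "
          f"n = {rich['n_used']} (median shift "
          f"{rich['median_shift']:+.1f} species)")
    for name in ("rG", "rL", "T"):
        s = summary[f"{name}_summary"]
        print(f"{name}: mean {s['mean']:.1f} +/- {s['sd']:.1f}, "
              f"median {s['median']:.1f} +/- {s['mad']:.1f} MAD "
              f"(n = {s['n']} protected areas)")
    d = summary["dPR_summary"]
    print(f"dPR: median {d['median']:.1f}% +/- {d['mad']:.1f} MAD over "
          f"{d['n']} species "
          f"({summary['n_species_excluded_dPR']} excluded: reference "
          "range off protected land)")
    print(f"{summary['n_pa_losing_richness']} protected areas would lose "
          "species richness")
    rp = summary.get("representativity_test_province")
    if rp:
        print("representativity at the province scale: "
              f"V = {rp['statistic']:.1f}, p = {rp['p_value']:.2e} "
              f"(median shift {rp['median_shift']:+.3f})")

    cfg.RESULTS_DIR.mkdir(exist_ok=True)
    for name in ("pa_impacts.csv", "protection_change.csv",
                 "land_distributions.csv"):
        shutil.copy(cfg.RUN_DIR / name, cfg.RESULTS_DIR / name)
    with open(cfg.RESULTS_DIR / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"summary tables copied to {cfg.RESULTS_DIR}")


if __name__ == "__main__":
    main()
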