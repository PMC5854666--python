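"""Screen climate predictors for collinearity, per taxon.

Keeps variables greedily in biological-relevance order so that every
retained pair has |Pearson r| < 0.6; tree species additionally carry the
two categorical soil covariates.
"""

import importlib

cfg = importlib.import_module("00_config")

from nicheshift.pipeline import stage_predictors  # noqa: E402


def main() -> None:
    info = stage_predictors(cfg.CONFIG, cfg.RUN_DIR)
    print("retained predictor sets (|r| < "
          f"{cfg.CONFIG.correlation_threshold} for all pairs):")
    for taxon, retained in info["retained"].items():
        print(f"  {taxon:12s} {', '.join(retained)}")


if __name__ == "__main__":
    main()
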