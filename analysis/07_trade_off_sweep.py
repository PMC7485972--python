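"""Sensitivity of the vulnerability-contribution slope to the trade-off.

Refits feasibility contributions and the mixed model across a grid of
delta values, asking over which trade-off regime the most vulnerable links
contribute most to feasibility.
"""

from pathlib import Path

from linkrisk.pipeline import RunConfig, run_delta_sweep
from linkrisk.synthetic import MetawebConfig

OUT = Path("results/sweep")
GRID = [0.0, 0.17, 0.339, 0.5, 0.75]


def main() -> None:
    cfg = RunConfig(output_dir=str(OUT), seed=1, synthetic=MetawebConfig(seed=1))
    sweep = run_delta_sweep(cfg, GRID)
    print("slope of contribution ~ vulnerability per trade-off value:")
    print(sweep.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
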