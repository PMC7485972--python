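"""Score every link's vulnerability V = (1 - f)(1 - D).

Fills the frequency, generalisation and vulnerability columns of the link
table written by 01_simulate_metaweb.py and summarises their distributions.
"""

from pathlib import Path

from linkrisk.pipeline import stage_vulnerability

OUT = Path("results/study")


def main() -> None:
    table = stage_vulnerability(OUT)
    print(f"annotated {len(table)} links across {table['network_id'].nunique()} networks")
    print(table[["f_std", "D_raw", "D_std", "V"]].describe().round(3).to_string())
    top = table.nlargest(5, "V")[["network_id", "plant", "animal", "weight", "V"]]
    print("\nmost vulnerable links (rare, specialist):")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
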