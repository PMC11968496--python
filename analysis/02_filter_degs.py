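"""Filter each DE table (adj_p < 0.05, FC > 1.5 or < 0.67) and intersect per tissue.

The intersection keeps genes found in every dataset regardless of direction.
Writes common_degs.txt per tissue.
"""

from common import TISSUES, tissue_dir

from dcx import degstage


def main() -> None:
    for tissue in TISSUES:
        out = tissue_dir(tissue)
        sets = []
        for path in sorted(out.glob("de_table_*.csv")):
            table = degstage.read_de_table(path)
            degs = degstage.filter_degs(table)
            sets.append(degs)
            print(f"{tissue}/{path.stem}: {len(degs.genes)} DEGs "
                  f"({sum(d == 'up' for d in degs.directions.values())} up)")
        common = sorted(degstage.intersect_degs(sets))
        (out / "common_degs.txt").write_text("\n".join(common) + "\n")
        print(f"{tissue}: {len(common)} common DEGs")


if __name__ == "__main__":
    main()
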