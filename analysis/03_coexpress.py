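"""Pairwise correlations per condition over the common DEGs, then the
differential edge set (p_critic gating + |SCCd - SCCh| > 0.5).
"""

import pandas as pd
from common import TISSUES, tissue_dir

from dcx import diffcoexp


def main() -> None:
    for tissue in TISSUES:
        out = tissue_dir(tissue)
        common = (out / "common_degs.txt").read_text().split()
        corr = {}
        for condition in ("disease", "healthy"):
            matrix = pd.read_csv(out / f"expression_{condition}.tsv", sep="\t", index_col=0)
            sub = matrix.loc[[g for g in common if g in matrix.index]]
            norm, dropped = diffcoexp.zscore_normalize(sub)
            if dropped:
                print(f"{tissue}/{condition}: dropped zero-variance genes {dropped}")
            corr[condition] = diffcoexp.pairwise_correlations(sub.loc[norm.index], condition)
            corr[condition].to_csv(out / f"correlations_{condition}.tsv", sep="\t", index=False)
            summary = diffcoexp.compute_p_critic(corr[condition])
            print(f"{tissue}/{condition}: {len(corr[condition])} pairs, "
                  f"mean|SCC|={summary.mean_scc:.3f}, p_critic={summary.p_critic:.3f}")
        edges = diffcoexp.differential_edges(corr["disease"], corr["healthy"])
        edges.to_csv(out / "differential_edges.tsv", sep="\t", index=False)
        print(f"{tissue}: {len(edges)} differential edges at epsilon=0.5")


if __name__ == "__main__":
    main()
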