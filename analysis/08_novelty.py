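"""Literature-novelty scoring.

Scores the cross-tissue candidate drugs on synthetic co-mention counts, then
re-derives the packaged 20-drug reference table's TF-IDF column and novel set
from its raw counts.
"""

from common import RESULTS, SEED

from dcx import litnovelty, synthdata


def main() -> None:
    candidates = (RESULTS / "common_candidates.txt").read_text().split()
    if candidates:
        counts = synthdata.generate_literature_counts(
            candidates, n_novel=min(2, len(candidates)), seed=SEED)
        report = litnovelty.novelty_report(litnovelty.score_novelty(counts))
        report.to_csv(RESULTS / "novelty_report.tsv", sep="\t", index=False)
        novel = report[report["novel"]]["drug"].tolist()
        print(f"synthetic candidates: {len(report)} scored, novel: {novel}")

    reference = litnovelty.load_table1()
    scores = litnovelty.novelty_report(litnovelty.score_novelty(reference))
    scores.to_csv(RESULTS / "reference_novelty_report.tsv", sep="\t", index=False)
    novel = scores[scores["novel"]]["drug"].tolist()
    print(f"reference table: co-mention total "
          f"{int(reference['n_disease_articles'].sum())}, novel drugs: {novel}")


if __name__ == "__main__":
    main()
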