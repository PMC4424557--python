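"""Top-N accuracy of candidate rankings against a gold lexicon.

A test term counts as a hit at N when its best-ranked acceptable gold
translation sits at rank <= N (exact TermType match — no credit for
merely "permissible" near-translations).  Terms whose gold translations
never occur in the target corpus can be reported separately, with an
accuracy variant that excludes them from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from bilex.context import CandidateRanking
from bilex.corpus_io import TermType

__all__ = ["AccuracyReport", "GoldLexicon", "top_n_accuracy"]

#: source term -> set of acceptable target translations
GoldLexicon = dict[TermType, set[TermType]]


@dataclass
class AccuracyReport:
    """Per-N accuracies with per-term hit ranks and bookkeeping counts."""

    n_values: list[int]
    accuracies: dict[int, float]
    hit_ranks: dict[TermType, int | None]
    unevaluable: list[TermType] = field(default_factory=list)
    gold_absent: list[TermType] = field(default_factory=list)
    accuracies_excluding_absent: dict[int, float] = field(default_factory=dict)

    @property
    def n_evaluated(self) -> int:
        return len(self.hit_ranks)

    def summary(self) -> str:
        lines = [f"evaluated terms: {self.n_evaluated}"]
        if self.unevaluable:
            lines.append(f"unevaluable (no gold entry): {len(self.unevaluable)}")
        if self.gold_absent:
            lines.append(
                f"gold translation absent from target corpus: {len(self.gold_absent)}"
            )
        for n in self.n_values:
            line = f"Acc_{n}: {self.accuracies[n]:.2%}"
            if self.accuracies_excluding_absent:
                line += (
                    f"  (excluding absent-gold terms:"
                    f" {self.accuracies_excluding_absent[n]:.2%})"
                )
            lines.append(line)
        return "\n".join(lines)


def _best_gold_rank(
    ranking: CandidateRanking, gold_targets: set[TermType]
) -> int | None:
    best = None
    for rank, (cand, _score) in enumerate(ranking.candidates, start=1):
        if cand in gold_targets and (best is None or rank < best):
            best = rank
    return best


def top_n_accuracy(
    rankings: dict[TermType, CandidateRanking],
    gold: GoldLexicon,
    Ns: list[int] | tuple[int, ...] = (1, 10, 100),
    target_vocabulary: set[TermType] | None = None,
) -> AccuracyReport:
    """Compute Acc_N over all ranked test terms that have a gold entry.

    Terms present in ``rankings`` but absent from ``gold`` are excluded
    and reported as unevaluable.  Terms with an empty ranking count as
    misses.  When ``target_vocabulary`` is given, test terms none of
    whose gold translations occur in the target corpus are additionally
    reported, and accuracies with those removed from the denominator are
    emitted alongside the strict ones.
    """
    n_values = sorted(set(Ns))
    if not n_values or n_values[0] < 1:
        raise ValueError("Ns must be positive integers")

    hit_ranks: dict[TermType, int | None] = {}
    unevaluable: list[TermType] = []
    gold_absent: list[TermType] = []
    for term, ranking in rankings.items():
        if term not in gold:
            unevaluable.append(term)
            continue
        hit_ranks[term] = _best_gold_rank(ranking, gold[term])
        if target_vocabulary is not None and not (gold[term] & target_vocabulary):
            gold_absent.append(term)

    total = len(hit_ranks)
    accuracies = {}
    for n in n_values:
        hits = sum(1 for r in hit_ranks.values() if r is not None and r <= n)
        accuracies[n] = hits / total if total else 0.0

    excl: dict[int, float] = {}
    if target_vocabulary is not None:
        absent = set(gold_absent)
        kept = {t: r for t, r in hit_ranks.items() if t not in absent}
        for n in n_values:
            hits = sum(1 for r in kept.values() if r is not None and r <= n)
            excl[n] = hits / len(kept) if kept else 0.0

    return AccuracyReport(
        n_values=n_values,
        accuracies=accuracies,
        hit_ranks=hit_ranks,
        unevaluable=unevaluable,
        gold_absent=gold_absent,
        accuracies_excluding_absent=excl,
    )


def write_report_tsv(report: AccuracyReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_evaluated\t{report.n_evaluated}\n")
        fh.write(f"n_unevaluable\t{len(report.unevaluable)}\n")
        fh.write(f"n_gold_absent\t{len(report.gold_absent)}\n")
        for n in report.n_values:
            fh.write(f"acc_{n}\t{report.accuracies[n]:.6f}\n")
        for n, v in sorted(report.accuracies_excluding_absent.items()):
            fh.write(f"acc_{n}_excluding_absent\t{v:.6f}\n")
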