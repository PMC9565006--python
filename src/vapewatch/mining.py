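"""FP-growth frequent itemset mining and pairwise association rules.

Tweets are reduced to *transactions* — deduplicated lowercase token sets with
punctuation substituted by spaces and stopwords removed.  Frequent itemsets
(absolute support >= ``min_support``) are mined with the FP-growth algorithm:
transactions are compressed into a prefix tree (FP-tree) whose items are
ordered by descending global frequency (ties broken lexicographically), and
itemsets are extracted by recursively building conditional trees, avoiding
apriori-style candidate generation.

From the frequent pairs, association rules x -> y are scored by
``support({x, y}) / support({x})`` — the conditional probability of seeing the
consequent given the antecedent.  The cessation lexicon is the set of
antecedents strongly associated with the anchor token ``vaping``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .preprocess import normalize_tokens


@dataclass(frozen=True, slots=True)
class Transaction:
    """Deduplicated token set of one tweet."""

    tokens: frozenset[str]
    tweet_id: str = ""


@dataclass(frozen=True, slots=True)
class FrequentItemset:
    items: tuple[str, ...]  # sorted
    support: int


@dataclass(frozen=True, slots=True)
class AssociationRule:
    antecedent: str
    consequent: str
    support: int  # absolute support of the pair
    rule_probability: float  # support(pair) / support(antecedent)


def tokenize(text: str, stopwords: Iterable[str] = ()) -> frozenset[str]:
    """Punctuation -> space, lowercase, split, drop stopwords, deduplicate."""
    stop = frozenset(stopwords)
    return frozenset(tok for tok in normalize_tokens(text) if tok not in stop)


def make_transactions(
    texts_with_ids: Iterable[tuple[str, str]], stopwords: Iterable[str]
) -> list[Transaction]:
    stop = frozenset(stopwords)
    return [Transaction(tokenize(text, stop), tweet_id) for tweet_id, text in texts_with_ids]


class _FPNode:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item: str | None, parent: "_FPNode | None"):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _FPNode] = {}


def _build_tree(
    itemlists: Iterable[tuple[Sequence[str], int]],
) -> dict[str, list[_FPNode]]:
    """Insert (ordered item list, count) pairs into a fresh FP-tree.

    Returns the header table: item -> list of tree nodes carrying it.  The
    root is implicit; mining only ever walks parent pointers from header
    nodes, so the root object itself need not be returned.
    """
    root = _FPNode(None, None)
    header: dict[str, list[_FPNode]] = defaultdict(list)
    for items, count in itemlists:
        node = root
        for item in items:
            child = node.children.get(item)
            if child is None:
                child = _FPNode(item, node)
                node.children[item] = child
                header[item].append(child)
            child.count += count
            node = child
    return header


def _mine(
    itemlists: list[tuple[list[str], int]],
    min_support: int,
    suffix: tuple[str, ...],
    out: dict[frozenset[str], int],
) -> None:
    # global (within this projection) item frequencies
    counts: dict[str, int] = defaultdict(int)
    for items, count in itemlists:
        for item in items:
            counts[item] += count
    frequent = {item: c for item, c in counts.items() if c >= min_support}
    if not frequent:
        return
    # descending frequency, ties lexicographic -> deterministic tree shape
    rank = {item: i for i, item in enumerate(sorted(frequent, key=lambda it: (-frequent[it], it)))}

    ordered = []
    for items, count in itemlists:
        kept = sorted((it for it in items if it in rank), key=rank.__getitem__)
        if kept:
            ordered.append((kept, count))
    header = _build_tree(ordered)

    # mine items from least to most frequent
    for item in sorted(rank, key=rank.__getitem__, reverse=True):
        support = sum(node.count for node in header[item])
        out[frozenset(suffix + (item,))] = support
        # conditional pattern base: prefix paths above each node carrying item
        conditional: list[tuple[list[str], int]] = []
        for node in header[item]:
            path: list[str] = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                path.reverse()
                conditional.append((path, node.count))
        if conditional:
            _mine(conditional, min_support, suffix + (item,), out)


def mine_frequent_itemsets(
    transactions: Sequence[Transaction | frozenset[str] | set[str]],
    min_support: int,
) -> list[FrequentItemset]:
    """All itemsets with absolute support >= ``min_support``, exact supports.

    Output is independent of transaction order and sorted by descending
    support, then lexicographically, for reproducible reports.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    itemlists: list[tuple[list[str], int]] = []
    for t in transactions:
        tokens = t.tokens if isinstance(t, Transaction) else frozenset(t)
        if tokens:
            itemlists.append((list(tokens), 1))
    found: dict[frozenset[str], int] = {}
    _mine(itemlists, min_support, (), found)
    result = [FrequentItemset(tuple(sorted(items)), support) for items, support in found.items()]
    result.sort(key=lambda fi: (-fi.support, fi.items))
    return result


def support_index(itemsets: Iterable[FrequentItemset]) -> dict[frozenset[str], int]:
    return {frozenset(fi.items): fi.support for fi in itemsets}


def derive_pair_rules(itemsets: Iterable[FrequentItemset]) -> list[AssociationRule]:
    """Both directed rules for every frequent pair.

    ``rule_probability`` is the confidence P(consequent | antecedent) =
    support(pair) / support(antecedent).  Anti-monotonicity guarantees both
    singletons of a frequent pair are themselves frequent, so their supports
    are always available.
    """
    index = support_index(itemsets)
    rules: list[AssociationRule] = []
    for fi in itemsets:
        if len(fi.items) != 2:
            continue
        x, y = fi.items
        for antecedent, consequent in ((x, y), (y, x)):
            ante_support = index.get(frozenset((antecedent,)))
            assert ante_support, "frequent pair with missing/zero singleton support"
            rules.append(
                AssociationRule(antecedent, consequent, fi.support, fi.support / ante_support)
            )
    rules.sort(key=lambda r: (-r.support, r.antecedent, r.consequent))
    return rules


def select_quit_keywords(
    rules: Iterable[AssociationRule],
    anchor: str = "vaping",
    min_support: int = 1000,
    min_rule_probability: float = 0.30,
) -> list[str]:
    """Antecedents tied to the anchor above both thresholds, by support desc.

    Threshold comparisons are inclusive (>=): a rule sitting exactly at the
    probability threshold is kept.
    """
    selected = [
        r
        for r in rules
        if r.consequent == anchor
        and r.support >= min_support
        and r.rule_probability >= min_rule_probability
    ]
    selected.sort(key=lambda r: (-r.support, r.antecedent))
    return [r.antecedent for r in selected]
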