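"""Synthetic fixtures for the whole coding pipeline.

Real inputs for this task — a licensed radiology lexicon, commercial
bilingual dictionaries, hospital report corpora — cannot ship with a test
suite, so this module generates structurally faithful stand-ins at toy
scale: a complete anatomical taxonomy, a lexicon of RID-coded concepts
named from taxonomy paths, a template corpus in which designated synonym
tokens are sampled interchangeably (so the embedding model can learn
them), overlapping bilingual glossaries with controlled typo corruption,
and a labeled synonym-pair benchmark spanning four regimes:

* ``glyph``: small character-edit variants (edit distance 1-3);
* ``token_subset``: token subset/superset variants;
* ``distributional``: a token swapped for a corpus-only alias with a
  different surface form (the "cranium"/"skull" situation);
* ``taxonomic``: names of sibling leaves (same parent).

Negatives are cross-parent concept pairs, a quarter of them adversarial:
different concepts whose names are within edit distance 3 (the
"right scapula"/"left scapula" trap).  Each regime defeats at least one
single similarity score, which is what makes the benchmark a meaningful
test of score fusion.

Source-language phrases are opaque identifiers (``zh_rid1001`` etc.): the
coding arithmetic operates entirely on the translated side, so the tests
only need a consistent source-to-target mapping.

All randomness flows from ``SynthConfig.seed`` through per-purpose child
generators, so regeneration under a fixed config is byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .lexicon import LexiconConcept, write_lexicon
from .similarity import levenshtein_distance
from .taxonomy import Taxonomy, write_taxonomy

# label pools; adjacent organ entries form confusable (small-edit) pairs
ORGANS = [
    "lung", "ilium", "ileum", "femur", "malleus",
    "malleolus", "perineum", "peritoneum", "cranium",
]
STRUCTURES = [
    "lobe", "segment", "margin", "border", "cortex",
    "fossa", "ramus", "crest", "apex",
]
MODIFIERS = [
    "superior", "inferior", "anterior", "interior", "medial",
    "mesial", "lateral", "proximal", "distal",
]

# corpus-only aliases: deliberately glyph-dissimilar surface forms
ALIASES = {
    "lung": "pulmo", "ilium": "haunch", "ileum": "gutloop", "femur": "thighbone",
    "malleus": "hammerbone", "malleolus": "anklebone", "perineum": "groinfloor",
    "peritoneum": "bellylining", "cranium": "skull",
    "lobe": "flap", "segment": "portion", "margin": "brink", "border": "fringe",
    "cortex": "rind", "fossa": "hollow", "ramus": "offshoot", "crest": "ridge",
    "apex": "summit",
    "superior": "upper", "inferior": "lower", "anterior": "front",
    "interior": "inside", "medial": "inward", "mesial": "midward",
    "lateral": "outward", "proximal": "nearward", "distal": "farward",
}

TEMPLATES = [
    "the <T> appears entirely normal",
    "no focal lesion is seen in the <T>",
    "mild opacity noted near the <T>",
    "the <T> is unremarkable on this study",
    "current scan shows the <T> clearly",
    "findings again involve the <T>",
    "impression stable appearance of the <T>",
    "the <T> demonstrates no interval change",
]

JUNK_TRANSLATIONS = [
    "routine paperwork item",
    "billing ledger entry",
    "archive folder note",
    "miscellaneous admin record",
    "schedule memo text",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class SynthConfig:
    """Knobs of the synthetic study; defaults are the reference conditions
    used throughout the test suite."""

    seed: int = 7
    n_concepts: int = 24
    taxonomy_branching: int = 3
    taxonomy_depth: int = 4
    corpus_sentences: int = 1500
    glossary_coverage: float = 1.0
    typo_rate: float = 0.1
    regime_mix: dict[str, float] = field(
        default_factory=lambda: {
            "glyph": 0.25,
            "token_subset": 0.25,
            "distributional": 0.25,
            "taxonomic": 0.25,
        }
    )
    n_pairs: int = 400
    negative_ratio: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.regime_mix.values()) - 1.0) > 1e-9:
            raise ValueError("regime_mix proportions must sum to 1")
        if set(self.regime_mix) != {"glyph", "token_subset", "distributional", "taxonomic"}:
            raise ValueError("regime_mix must cover exactly the four regimes")
        for name in ("n_concepts", "taxonomy_branching", "taxonomy_depth",
                     "corpus_sentences", "n_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.glossary_coverage <= 1.0:
            raise ValueError("glossary_coverage must be in [0, 1]")
        if not 0.0 <= self.typo_rate <= 1.0:
            raise ValueError("typo_rate must be in [0, 1]")
        if self.negative_ratio < 1.0:
            raise ValueError("negative_ratio must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for one purpose; streams never interact."""
        return np.random.default_rng([self.seed, stream])


class PairExample(NamedTuple):
    a: str
    b: str
    label: int
    regime: str


# ----------------------------------------------------------------- taxonomy
def make_taxonomy(cfg: SynthConfig) -> Taxonomy:
    """Complete tree of the configured branching and depth.

    Level 2 nodes take organ labels, the leaf level takes positional
    modifiers, intermediate levels take structure labels; sibling groups
    draw from the pools at staggered offsets so the same word labels nodes
    under different parents (exercising the max-sense rule downstream).
    """
    b, depth = cfg.taxonomy_branching, cfg.taxonomy_depth
    if b < 2 or depth < 2:
        raise ValueError("taxonomy_branching and taxonomy_depth must be >= 2")
    if b > len(ORGANS):
        raise ValueError(f"taxonomy_branching must be <= {len(ORGANS)}")
    parent: dict[str, str | None] = {"n0": None}
    labels: dict[str, str] = {"n0": "entity"}
    level_nodes = ["n0"]
    counter = 1
    for level in range(2, depth + 1):
        if level == 2:
            pool = ORGANS
        elif level == depth:
            pool = MODIFIERS
        else:
            pool = STRUCTURES
        next_level: list[str] = []
        for parent_seq, par in enumerate(level_nodes):
            for j in range(b):
                node = f"n{counter}"
                counter += 1
                parent[node] = par
                labels[node] = pool[(parent_seq + j) % len(pool)]
                next_level.append(node)
        level_nodes = next_level
    return Taxonomy(parent, labels)


def concept_name(tax: Taxonomy, leaf: str) -> str:
    """Readable name from the leaf's label path, e.g. 'superior lobe of lung'."""
    chain = [tax.labels[n] for n in tax.ancestors(leaf)[:-1]]  # leaf .. level2
    if len(chain) == 1:
        return chain[0]
    return " ".join(chain[:-1]) + " of " + chain[-1]


# ------------------------------------------------------------------ lexicon
def corrupt_phrase(phrase: str, rng: np.random.Generator, n_edits: int) -> str:
    """Apply 1-3 character edits inside tokens of length >= 4.

    Whole tokens are never deleted, so multi-word phrases stay multi-word
    and each edit changes the true edit distance by at most 1.
    """
    tokens = phrase.split()
    eligible = [i for i, t in enumerate(tokens) if len(t) >= 4]
    if not eligible:
        raise ValueError(f"no corruptible token in {phrase!r}")
    for _ in range(n_edits):
        ti = eligible[rng.integers(len(eligible))]
        tok = tokens[ti]
        op = rng.integers(3) if len(tok) > 4 else rng.integers(2)
        pos = int(rng.integers(len(tok)))
        if op == 0:  # substitute with a different letter
            new = tok[pos]
            while new == tok[pos]:
                new = _LETTERS[rng.integers(26)]
            tok = tok[:pos] + new + tok[pos + 1 :]
        elif op == 1:  # insert
            tok = tok[:pos] + _LETTERS[rng.integers(26)] + tok[pos:]
        else:  # delete one character (token stays >= 4 chars)
            tok = tok[:pos] + tok[pos + 1 :]
        tokens[ti] = tok
    out = " ".join(tokens)
    return out if out != phrase else corrupt_phrase(phrase, rng, 1)


def _select_leaves(cfg: SynthConfig, tax: Taxonomy) -> list[str]:
    leaves = tax.leaves()
    if cfg.n_concepts > len(leaves):
        raise ValueError(
            f"n_concepts={cfg.n_concepts} exceeds taxonomy leaf count {len(leaves)}"
        )
    rng = cfg.rng(10)
    chosen = sorted(rng.choice(len(leaves), size=cfg.n_concepts, replace=False).tolist())
    return [leaves[i] for i in chosen]


def make_lexicon(cfg: SynthConfig, tax: Taxonomy) -> list[LexiconConcept]:
    """One RID-coded concept per selected leaf, with 0-2 synonyms each
    (a glyph variant within edit distance 3 and/or a token-superset
    variant)."""
    leaves = _select_leaves(cfg, tax)
    rng = cfg.rng(11)
    concepts: list[LexiconConcept] = []
    seen_terms: set[str] = set()
    for i, leaf in enumerate(leaves):
        name = concept_name(tax, leaf)
        synonyms: list[str] = []
        if rng.random() < 0.6:  # glyph synonym
            for _ in range(5):
                variant = corrupt_phrase(name, rng, int(rng.integers(1, 4)))
                if variant not in seen_terms and variant != name:
                    synonyms.append(variant)
                    break
        if rng.random() < 0.5:  # token-superset synonym
            side = "left" if rng.random() < 0.5 else "right"
            variant = f"{side} {name}"
            if variant not in seen_terms:
                synonyms.append(variant)
        seen_terms.add(name)
        seen_terms.update(synonyms)
        concepts.append(LexiconConcept(f"RID{1001 + i}", name, tuple(synonyms)))
    return concepts


def concept_leaf_map(cfg: SynthConfig, tax: Taxonomy) -> dict[str, str]:
    """code -> leaf node id, consistent with :func:`make_lexicon`."""
    leaves = _select_leaves(cfg, tax)
    return {f"RID{1001 + i}": leaf for i, leaf in enumerate(leaves)}


# ------------------------------------------------------------------- corpus
def distributional_aliases(lexicon: Sequence[LexiconConcept]) -> dict[str, str]:
    """Alias map restricted to words actually used by the lexicon."""
    used = {t for c in lexicon for t in c.preferred_name.split()}
    return {w: a for w, a in ALIASES.items() if w in used}


def make_corpus(cfg: SynthConfig, lexicon: Sequence[LexiconConcept]) -> list[list[str]]:
    """Template sentences embedding concept names.

    Each aliasable token is independently replaced by its alias with
    probability 1/2, so a word and its alias occur in identical contexts —
    the co-occurrence signal the CBOW model is meant to pick up.
    """
    rng = cfg.rng(2)
    aliases = distributional_aliases(lexicon)
    corpus: list[list[str]] = []
    for _ in range(cfg.corpus_sentences):
        concept = lexicon[rng.integers(len(lexicon))]
        term_tokens = [
            aliases[t] if t in aliases and rng.random() < 0.5 else t
            for t in concept.preferred_name.split()
        ]
        template = TEMPLATES[rng.integers(len(TEMPLATES))].split()
        sent: list[str] = []
        for w in template:
            if w == "<T>":
                sent.extend(term_tokens)
            else:
                sent.append(w)
        corpus.append(sent)
    return corpus


# --------------------------------------------------------------- glossaries
def source_phrase(code: str) -> str:
    """Opaque source-language identifier for a concept."""
    return f"zh_{code.lower()}"


def make_glossaries(
    cfg: SynthConfig, lexicon: Sequence[LexiconConcept]
) -> list[list[tuple[str, str]]]:
    """Two overlapping glossary files with controlled corruption.

    A ``glossary_coverage`` fraction of concepts appears; each target is
    corrupted by 1-3 character edits with probability ``typo_rate``
    (multi-word targets only, so corrupted entries stay recoverable by the
    fuzzy extraction rule).  About a fifth of the pairs are written to both
    files to exercise deduplication.
    """
    rng = cfg.rng(3)
    n_cov = int(round(cfg.glossary_coverage * len(lexicon)))
    covered_idx = sorted(rng.choice(len(lexicon), size=n_cov, replace=False).tolist())
    files: list[list[tuple[str, str]]] = [[], []]
    for i in covered_idx:
        concept = lexicon[i]
        src = source_phrase(concept.code)
        targets = [concept.preferred_name]
        if concept.synonyms and rng.random() < 0.3:
            targets.append(concept.synonyms[int(rng.integers(len(concept.synonyms)))])
        for tgt in targets:
            if len(tgt.split()) > 1 and rng.random() < cfg.typo_rate:
                tgt = corrupt_phrase(tgt, rng, int(rng.integers(1, 4)))
            u = rng.random()
            if u < 0.4:
                files[0].append((src, tgt))
            elif u < 0.8:
                files[1].append((src, tgt))
            else:  # deliberate overlap
                files[0].append((src, tgt))
                files[1].append((src, tgt))
    return files


def n_nomatch_phrases(cfg: SynthConfig) -> int:
    return max(2, int(round(0.1 * cfg.n_concepts)))


def make_mock_translations(
    cfg: SynthConfig, lexicon: Sequence[LexiconConcept]
) -> dict[str, list[str]]:
    """External-translator table emulating fluent but imperfect output.

    Concept phrases mostly translate to the preferred name, sometimes to a
    qualified variant, occasionally to a different concept's name (the
    machine-translation error mode).  NO_MATCH phrases translate to
    out-of-domain boilerplate.
    """
    rng = cfg.rng(6)
    table: dict[str, list[str]] = {}
    for concept in lexicon:
        u = rng.random()
        if u < 0.75:
            out = concept.preferred_name
        elif u < 0.9:
            side = "left" if rng.random() < 0.5 else "right"
            out = f"{side} {concept.preferred_name}"
        else:
            other = lexicon[int(rng.integers(len(lexicon)))]
            out = other.preferred_name
        table[source_phrase(concept.code)] = [out]
    for i in range(n_nomatch_phrases(cfg)):
        table[f"zh_nomatch_{i}"] = [
            JUNK_TRANSLATIONS[int(rng.integers(len(JUNK_TRANSLATIONS)))]
        ]
    return table


def make_gold(cfg: SynthConfig, lexicon: Sequence[LexiconConcept]) -> dict[str, str]:
    """Gold standard: every concept phrase maps to its code, plus the
    designated NO_MATCH phrases."""
    gold = {source_phrase(c.code): c.code for c in lexicon}
    for i in range(n_nomatch_phrases(cfg)):
        gold[f"zh_nomatch_{i}"] = "NO_MATCH"
    return gold


# ------------------------------------------------------------ labeled pairs
def make_labeled_pairs(
    cfg: SynthConfig, lexicon: Sequence[LexiconConcept], tax: Taxonomy
) -> list[PairExample]:
    """``n_pairs`` positives split across the four regimes, plus
    ``n_pairs * negative_ratio`` cross-parent negatives (a quarter of them
    adversarial glyph-similar pairs when such pairs exist)."""
    rng = cfg.rng(4)
    aliases = distributional_aliases(lexicon)
    leaf_of = concept_leaf_map(cfg, tax)
    parent_of = {c.code: tax.parent[leaf_of[c.code]] for c in lexicon}

    sibling_pairs = [
        (i, j)
        for i in range(len(lexicon))
        for j in range(i + 1, len(lexicon))
        if parent_of[lexicon[i].code] == parent_of[lexicon[j].code]
    ]
    cross_pairs = [
        (i, j)
        for i in range(len(lexicon))
        for j in range(i + 1, len(lexicon))
        if parent_of[lexicon[i].code] != parent_of[lexicon[j].code]
    ]
    adversarial_pairs = [
        (i, j)
        for i, j in cross_pairs
        if levenshtein_distance(lexicon[i].preferred_name, lexicon[j].preferred_name) <= 3
    ]
    aliasable = [
        i
        for i, c in enumerate(lexicon)
        if any(t in aliases for t in c.preferred_name.split())
    ]

    order = ("glyph", "token_subset", "distributional", "taxonomic")
    counts = {r: int(cfg.n_pairs * cfg.regime_mix[r]) for r in order}
    leftover = cfg.n_pairs - sum(counts.values())
    for r in order[:leftover]:
        counts[r] += 1

    examples: list[PairExample] = []
    for _ in range(counts["glyph"]):
        c = lexicon[int(rng.integers(len(lexicon)))]
        if rng.random() < 0.3:
            # the completely-identical case: glossary terms are most often
            # written exactly as the lexicon term, and the classifier must
            # rank that region above every perturbed one
            variant = c.preferred_name
        else:
            variant = corrupt_phrase(c.preferred_name, rng, int(rng.integers(1, 4)))
        examples.append(PairExample(c.preferred_name, variant, 1, "glyph"))
    for _ in range(counts["token_subset"]):
        c = lexicon[int(rng.integers(len(lexicon)))]
        tokens = c.preferred_name.split()
        if len(tokens) >= 3 and rng.random() < 0.5:
            variant = " ".join(tokens[1:])  # drop the leading qualifier
        else:
            side = "left" if rng.random() < 0.5 else "right"
            variant = f"{side} {c.preferred_name}"
        examples.append(PairExample(c.preferred_name, variant, 1, "token_subset"))
    for _ in range(counts["distributional"]):
        c = lexicon[aliasable[int(rng.integers(len(aliasable)))]]
        tokens = c.preferred_name.split()
        swappable = [k for k, t in enumerate(tokens) if t in aliases]
        k = swappable[int(rng.integers(len(swappable)))]
        variant = " ".join(aliases[t] if idx == k else t for idx, t in enumerate(tokens))
        examples.append(PairExample(c.preferred_name, variant, 1, "distributional"))
    for _ in range(counts["taxonomic"]):
        i, j = sibling_pairs[int(rng.integers(len(sibling_pairs)))]
        examples.append(
            PairExample(lexicon[i].preferred_name, lexicon[j].preferred_name, 1, "taxonomic")
        )

    n_neg = int(round(cfg.n_pairs * cfg.negative_ratio))
    n_adv = min(n_neg // 4, len(adversarial_pairs) * 4)
    if not adversarial_pairs:
        n_adv = 0
    for _ in range(n_adv):
        i, j = adversarial_pairs[int(rng.integers(len(adversarial_pairs)))]
        examples.append(
            PairExample(
                lexicon[i].preferred_name, lexicon[j].preferred_name, 0, "adversarial"
            )
        )
    for _ in range(n_neg - n_adv):
        i, j = cross_pairs[int(rng.integers(len(cross_pairs)))]
        a = lexicon[i].preferred_name
        other = lexicon[j]
        if other.synonyms and rng.random() < 0.3:
            b = other.synonyms[int(rng.integers(len(other.synonyms)))]
        else:
            b = other.preferred_name
        examples.append(PairExample(a, b, 0, "random"))

    perm = rng.permutation(len(examples))
    return [examples[int(k)] for k in perm]


# ------------------------------------------------------------------- output
def write_fixtures(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every fixture and write it under ``outdir``.

    Produces taxonomy.tsv, lexicon.tsv, corpus.txt, glossary_1.tsv,
    glossary_2.tsv, pairs.csv, gold.tsv, phrases.txt and
    mock_translation.tsv; returns the path of each.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tax = make_taxonomy(cfg)
    lexicon = make_lexicon(cfg, tax)
    corpus = make_corpus(cfg, lexicon)
    glossaries = make_glossaries(cfg, lexicon)
    pairs = make_labeled_pairs(cfg, lexicon, tax)
    gold = make_gold(cfg, lexicon)
    mock = make_mock_translations(cfg, lexicon)

    paths = {name: outdir / fname for name, fname in [
        ("taxonomy", "taxonomy.tsv"), ("lexicon", "lexicon.tsv"),
        ("corpus", "corpus.txt"), ("glossary_1", "glossary_1.tsv"),
        ("glossary_2", "glossary_2.tsv"), ("pairs", "pairs.csv"),
        ("gold", "gold.tsv"), ("phrases", "phrases.txt"),
        ("mock_translation", "mock_translation.tsv"),
    ]}
    write_taxonomy(tax, paths["taxonomy"])
    write_lexicon(lexicon, paths["lexicon"])
    paths["corpus"].write_text(
        "".join(" ".join(s) + "\n" for s in corpus), encoding="utf-8"
    )
    for key, rows in zip(("glossary_1", "glossary_2"), glossaries):
        with paths[key].open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerows(rows)
    with paths["pairs"].open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["a", "b", "label", "regime"])
        w.writerows(pairs)
    with paths["gold"].open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerows(gold.items())
    paths["phrases"].write_text(
        "".join(p + "\n" for p in gold), encoding="utf-8"
    )
    with paths["mock_translation"].open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for src, outs in mock.items():
            for out in outs:
                w.writerow([src, out])
    return paths
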