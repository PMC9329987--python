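"""Independent brute-force oracles used to check the vectorized encoders and
the metric implementations.

Everything here enumerates windows, patterns or sample pairs naively with
Python loops and dictionaries; none of it shares code with the package paths
it verifies.
"""

from __future__ import annotations

import itertools
import math

ALPHABET = "ACGU"
COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335}


def windows(s: str, k: int) -> list[str]:
    return [s[i : i + k] for i in range(len(s) - k + 1)]


def _tally(items) -> dict:
    counts: dict = {}
    for item in items:
        counts[item] = counts.get(item, 0) + 1
    return counts


def naive_kmer(s: str, k: int) -> dict[str, float]:
    names = ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]
    wins = windows(s, k)
    counts = _tally(wins)
    return {name: counts.get(name, 0) / len(wins) for name in names}


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def canonical(kmer: str) -> str:
    return min(kmer, revcomp(kmer))


def canonical_set(k: int) -> list[str]:
    return sorted({canonical("".join(p)) for p in itertools.product(ALPHABET, repeat=k)})


def naive_rckmer(s: str, k: int) -> dict[str, float]:
    wins = [canonical(w) for w in windows(s, k)]
    counts = _tally(wins)
    return {name: counts.get(name, 0) / len(wins) for name in canonical_set(k)}


def naive_pseudoknc(s: str, K: int) -> dict[str, float]:
    out: dict[str, float] = {}
    for i in range(1, K + 1):
        out.update(naive_kmer(s, i))
    return out


def naive_zcurve(s: str) -> dict[str, float]:
    a, c, g, u = (s.count(b) for b in ALPHABET)
    return {"x": (a + g) - (c + u), "y": (a + c) - (g + u), "z": (a + u) - (g + c)}


def naive_eiip(s: str) -> dict[str, float]:
    freq = naive_kmer(s, 3)
    return {t: sum(EIIP[c] for c in t) * f for t, f in freq.items()}


def _naive_kgap(s: str, head: int, G: int) -> dict[str, float]:
    out: dict[str, float] = {}
    head_names = ["".join(p) for p in itertools.product(ALPHABET, repeat=head)]
    for g in range(1, G + 1):
        span = head + g + 1
        found: list[tuple[str, str]] = []
        for i in range(len(s) - span + 1):
            found.append((s[i : i + head], s[i + head + g]))
        n = len(found)
        counts = _tally(found)
        for h in head_names:
            for t in ALPHABET:
                out[f"{h}_g{g}_{t}"] = counts.get((h, t), 0) / n if n else 0.0
    return out


def naive_dimonokgap(s: str, G: int) -> dict[str, float]:
    return _naive_kgap(s, 2, G)


def naive_trimonokgap(s: str, G: int) -> dict[str, float]:
    return _naive_kgap(s, 3, G)


def random_rna(rng, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


# --- metric oracles -----------------------------------------------------------

def ovr_tallies(true: list[str], pred: list[str], label: str) -> tuple[int, int, int, int]:
    tp = sum(1 for t, p in zip(true, pred) if t == label and p == label)
    tn = sum(1 for t, p in zip(true, pred) if t != label and p != label)
    fp = sum(1 for t, p in zip(true, pred) if t != label and p == label)
    fn = sum(1 for t, p in zip(true, pred) if t == label and p != label)
    return tp, tn, fp, fn


def naive_macro_metrics(true: list[str], pred: list[str]) -> dict[str, float]:
    present = sorted(set(true) | set(pred))
    sps, f1s, mccs = [], [], []
    for label in present:
        tp, tn, fp, fn = ovr_tallies(true, pred, label)
        sps.append(tn / (tn + fp) if tn + fp else 0.0)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mccs.append((tp * tn - fp * fn) / den if den else 0.0)
    n = len(present)
    return {
        "accuracy": sum(1 for t, p in zip(true, pred) if t == p) / len(true),
        "specificity_macro": sum(sps) / n,
        "f1_macro": sum(f1s) / n,
        "mcc_macro": sum(mccs) / n,
    }


def naive_auroc(pos_scores: list[float], neg_scores: list[float]) -> float:
    """Exhaustive concordant/discordant pair counting with half credit for ties."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
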