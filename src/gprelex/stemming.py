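"""Porter stemming.

A self-contained implementation of the classic Porter (1980) suffix-stripping
algorithm, used uniformly for the relationship-term lexicon and for sentence
tokens so that lexicon lookup is robust to inflection ("associated",
"association", "associates" all reduce to "associ").

The implementation follows the original five-step description: within a step
the longest matching suffix is selected, and if its measure condition fails no
shorter suffix of that step is tried.  One deliberate variant: a single pass
of the original algorithm is not idempotent (e.g. "causes" -> "caus" -> "cau"),
so :func:`stem` iterates the pass to a fixed point.  This keeps lexicon lookup
stable when already-stemmed strings are stemmed again.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(fragment: str) -> int:
    """Number of VC sequences in the [C](VC)^m[V] decomposition."""
    m = 0
    i = 0
    n = len(fragment)
    while i < n and _is_consonant(fragment, i):
        i += 1
    while i < n:
        while i < n and not _is_consonant(fragment, i):
            i += 1
        if i >= n:
            break
        m += 1
        while i < n and _is_consonant(fragment, i):
            i += 1
    return m


def _contains_vowel(fragment: str) -> bool:
    return any(not _is_consonant(fragment, i) for i in range(len(fragment)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _apply_rules(word: str, rules, min_measure: int) -> str:
    """Apply the longest-matching rule whose stem measure exceeds the bound."""
    best = None
    for suffix, replacement in rules:
        if word.endswith(suffix) and (best is None or len(suffix) > len(best[0])):
            best = (suffix, replacement)
    if best is None:
        return word
    suffix, replacement = best
    stem_part = word[: len(word) - len(suffix)]
    if _measure(stem_part) > min_measure:
        return stem_part + replacement
    return word


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4_SUFFIXES = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def stem(word: str) -> str:
    """Return the lowercase Porter stem of ``word``; idempotent.

    Words of length <= 2 are returned unchanged (lowercased), as in the
    original algorithm.  The single-pass transformation is iterated until it
    stabilizes, which makes the function idempotent.
    """
    if not word:
        raise ValueError("cannot stem an empty string")
    w = word.lower()
    while True:
        nxt = _porter_pass(w)
        if nxt == w:
            return w
        w = nxt


def _porter_pass(w: str) -> str:
    if len(w) <= 2 or not w.isalpha():
        return w

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        stripped = None
        if w.endswith("ed") and _contains_vowel(w[:-2]):
            stripped = w[:-2]
        elif w.endswith("ing") and _contains_vowel(w[:-3]):
            stripped = w[:-3]
        if stripped is not None:
            w = stripped
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_consonant(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # Step 1c
    if w.endswith("y") and _contains_vowel(w[:-1]):
        w = w[:-1] + "i"

    w = _apply_rules(w, _STEP2, 0)
    w = _apply_rules(w, _STEP3, 0)

    # Step 4: drop the longest matching suffix when m > 1 ("ion" only after s/t)
    best = max((s for s in _STEP4_SUFFIXES if w.endswith(s)), key=len, default=None)
    if best is not None:
        stem_part = w[: len(w) - len(best)]
        if _measure(stem_part) > 1 and (best != "ion" or stem_part[-1:] in ("s", "t")):
            w = stem_part

    # Step 5a
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _ends_cvc(w[:-1])):
            w = w[:-1]
    # Step 5b
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        w = w[:-1]
    return w
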