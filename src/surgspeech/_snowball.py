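"""Snowball stemming algorithms (Spanish, English/Porter2).

Self-contained implementations of the published Snowball algorithm
definitions.  Words are assumed lowercase; the Spanish stemmer removes
acute accents as its final step, per the algorithm.
"""

from __future__ import annotations

__all__ = ["spanish_stem", "english_stem"]


# --------------------------------------------------------------------------
# Spanish
# --------------------------------------------------------------------------

_ES_VOWELS = set("aeiouáéíóúü")


def _es_r1_r2(word: str) -> tuple[int, int]:
    def region_after(start: int) -> int:
        for i in range(start + 1, len(word)):
            if word[i] not in _ES_VOWELS and word[i - 1] in _ES_VOWELS:
                return i + 1
        return len(word)

    r1 = region_after(0)
    r2 = region_after(r1 - 1) if r1 < len(word) else len(word)
    return r1, r2


def _es_rv(word: str) -> int:
    if len(word) < 3:
        return len(word)
    if word[1] not in _ES_VOWELS:
        for i in range(2, len(word)):
            if word[i] in _ES_VOWELS:
                return i + 1
        return len(word)
    if word[0] in _ES_VOWELS and word[1] in _ES_VOWELS:
        for i in range(2, len(word)):
            if word[i] not in _ES_VOWELS:
                return i + 1
        return len(word)
    return 3


def _in_region(word: str, suffix: str, region_start: int) -> bool:
    return word.endswith(suffix) and len(word) - len(suffix) >= region_start


_ES_PRONOUNS = sorted(
    ["me", "se", "sela", "selo", "selas", "selos", "la", "le", "lo",
     "las", "les", "los", "nos"],
    key=len, reverse=True,
)
_ES_PRON_PRE_A = ["iéndo", "ándo", "ár", "ér", "ír"]
_ES_PRON_PRE_B = ["ando", "iendo", "ar", "er", "ir"]
_ES_DEACCENT_PRE = {"iéndo": "iendo", "ándo": "ando", "ár": "ar",
                    "ér": "er", "ír": "ir"}

# (suffixes, action): action "delete" or replacement string; each group may
# define extra "preceded-by" deletions applied after the main action.
_ES_STEP1 = [
    (["anza", "anzas", "ico", "ica", "icos", "icas", "ismo", "ismos",
      "able", "ables", "ible", "ibles", "ista", "istas", "oso", "osa",
      "osos", "osas", "amiento", "amientos", "imiento", "imientos"],
     "delete", []),
    (["adora", "ador", "ación", "adoras", "adores", "aciones",
      "ante", "antes", "ancia", "ancias"], "delete", ["ic"]),
    (["logía", "logías"], "log", []),
    (["ución", "uciones"], "u", []),
    (["encia", "encias"], "ente", []),
    (["mente"], "delete", ["ante", "able", "ible"]),
    (["idad", "idades"], "delete", ["abil", "ic", "iv"]),
    (["iva", "ivo", "ivas", "ivos"], "delete", ["at"]),
]

_ES_STEP2A = sorted(
    ["ya", "ye", "yan", "yen", "yeron", "yendo", "yo", "yó", "yas",
     "yes", "yais", "yamos"],
    key=len, reverse=True,
)

_ES_STEP2B_GU = ["en", "es", "éis", "emos"]
_ES_STEP2B = sorted(
    ["arían", "arías", "arán", "arás", "aríais", "aría", "aréis",
     "aríamos", "aremos", "ará", "aré", "erían", "erías", "erán",
     "erás", "eríais", "ería", "eréis", "eríamos", "eremos", "erá",
     "eré", "irían", "irías", "irán", "irás", "iríais", "iría",
     "iréis", "iríamos", "iremos", "irá", "iré", "aba", "ada", "ida",
     "ía", "ara", "iera", "ad", "ed", "id", "ase", "iese", "aste",
     "iste", "an", "aban", "ían", "aran", "ieran", "asen", "iesen",
     "aron", "ieron", "ado", "ido", "ando", "iendo", "ió", "ar", "er",
     "ir", "as", "abas", "adas", "idas", "ías", "aras", "ieras",
     "ases", "ieses", "ís", "áis", "abais", "íais", "arais", "ierais",
     "aseis", "ieseis", "asteis", "isteis", "ados", "idos", "amos",
     "ábamos", "íamos", "imos", "áramos", "iéramos", "iésemos",
     "ásemos"] + _ES_STEP2B_GU,
    key=len, reverse=True,
)

_ES_ACCENT_MAP = str.maketrans("áéíóú", "aeiou")


def spanish_stem(word: str) -> str:
    if len(word) <= 2:
        return word.translate(_ES_ACCENT_MAP)
    rv = _es_rv(word)

    # Step 0: attached pronoun
    for pron in _ES_PRONOUNS:
        if not _in_region(word, pron, rv):
            continue
        stem = word[: -len(pron)]
        matched = False
        for pre in _ES_PRON_PRE_A:
            if _in_region(stem, pre, rv):
                word = stem[: -len(pre)] + _ES_DEACCENT_PRE[pre]
                matched = True
                break
        if not matched:
            for pre in _ES_PRON_PRE_B:
                if _in_region(stem, pre, rv):
                    word = stem
                    matched = True
                    break
        if not matched and _in_region(stem, "yendo", rv) and stem.endswith("uyendo"):
            word = stem
            matched = True
        if matched:
            rv = _es_rv(word)
        break

    r1, r2 = _es_r1_r2(word)
    changed = False

    # Step 1: standard suffixes (longest match over all groups)
    best: tuple[str, str, list[str]] | None = None
    for suffixes, action, also in _ES_STEP1:
        for suf in suffixes:
            if word.endswith(suf) and (best is None or len(suf) > len(best[0])):
                best = (suf, action, also)
    # "amente" has its own rule and outranks "mente" by length
    if word.endswith("amente") and (best is None or len("amente") > len(best[0])):
        best = ("amente", "_amente", [])
    if best is not None:
        suf, action, also = best
        if action == "_amente":
            if _in_region(word, suf, r1):
                word = word[: -len(suf)]
                changed = True
                if _in_region(word, "iv", r2):
                    word = word[:-2]
                    if _in_region(word, "at", r2):
                        word = word[:-2]
                else:
                    for pre in ("os", "ic", "ad"):
                        if _in_region(word, pre, r2):
                            word = word[: -len(pre)]
                            break
        elif _in_region(word, suf, r2):
            word = word[: -len(suf)] if action == "delete" else \
                word[: -len(suf)] + action
            changed = True
            for pre in also:
                if _in_region(word, pre, r2):
                    word = word[: -len(pre)]
                    break

    # Step 2a: verb suffixes beginning y (only if step 1 removed nothing)
    if not changed:
        rv = _es_rv(word)
        for suf in _ES_STEP2A:
            if _in_region(word, suf, rv) and word[: -len(suf)].endswith("u"):
                word = word[: -len(suf)]
                changed = True
                break

    # Step 2b: other verb suffixes (only if 2a removed nothing)
    if not changed:
        rv = _es_rv(word)
        for suf in _ES_STEP2B:
            if _in_region(word, suf, rv):
                word = word[: -len(suf)]
                if suf in _ES_STEP2B_GU and word.endswith("gu"):
                    word = word[:-1]
                break

    # Step 3: residual suffix
    rv = _es_rv(word)
    for suf in ("os", "a", "o", "á", "í", "ó"):
        if _in_region(word, suf, rv):
            word = word[: -len(suf)]
            break
    else:
        for suf in ("e", "é"):
            if _in_region(word, suf, rv):
                word = word[: -len(suf)]
                if word.endswith("gu") and len(word) - 1 >= rv:
                    word = word[:-1]
                break

    return word.translate(_ES_ACCENT_MAP)


# --------------------------------------------------------------------------
# English (Porter2)
# --------------------------------------------------------------------------

_EN_VOWELS = set("aeiouy")
_EN_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_EN_LI_END = set("cdeghkmnrt")

_EN_EXCEPTIONS = {
    "skis": "ski", "skies": "sky", "dying": "die", "lying": "lie",
    "tying": "tie", "idly": "idl", "gently": "gentl", "ugly": "ugli",
    "early": "earli", "only": "onli", "singly": "singl",
    "sky": "sky", "news": "news", "howe": "howe", "atlas": "atlas",
    "cosmos": "cosmos", "bias": "bias", "andes": "andes",
}
_EN_EXCEPTIONS_1A = {
    "inning", "outing", "canning", "herring", "earring",
    "proceed", "exceed", "succeed",
}

_EN_STEP2 = sorted(
    [("ization", "ize"), ("ational", "ate"), ("fulness", "ful"),
     ("ousness", "ous"), ("iveness", "ive"), ("tional", "tion"),
     ("biliti", "ble"), ("lessli", "less"), ("entli", "ent"),
     ("ation", "ate"), ("alism", "al"), ("aliti", "al"),
     ("ousli", "ous"), ("iviti", "ive"), ("fulli", "ful"),
     ("enci", "ence"), ("anci", "ance"), ("abli", "able"),
     ("izer", "ize"), ("ator", "ate"), ("alli", "al"),
     ("bli", "ble"), ("ogi", "og"), ("li", "")],
    key=lambda kv: len(kv[0]), reverse=True,
)
_EN_STEP3 = sorted(
    [("ational", "ate"), ("tional", "tion"), ("alize", "al"),
     ("icate", "ic"), ("iciti", "ic"), ("ative", ""), ("ical", "ic"),
     ("ful", ""), ("ness", "")],
    key=lambda kv: len(kv[0]), reverse=True,
)
_EN_STEP4 = sorted(
    ["al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
     "ment", "ent", "ism", "ate", "iti", "ous", "ive", "ize", "ion"],
    key=len, reverse=True,
)


def _en_r1_r2(word: str) -> tuple[int, int]:
    def region_after(start: int) -> int:
        for i in range(start + 1, len(word)):
            if word[i] not in _EN_VOWELS and word[i - 1] in _EN_VOWELS:
                return i + 1
        return len(word)

    r1 = len(word)
    for prefix in ("gener", "commun", "arsen"):
        if word.startswith(prefix):
            r1 = len(prefix)
            break
    else:
        r1 = region_after(0)
    r2 = region_after(r1 - 1) if r1 < len(word) else len(word)
    return r1, r2


def _en_short_syllable_at_end(word: str) -> bool:
    # vowel + non-vowel(not w/x/Y) preceded by non-vowel, at the end;
    # or the word is exactly vowel + non-vowel.
    if len(word) == 2:
        return word[0] in _EN_VOWELS and word[1] not in _EN_VOWELS
    if len(word) >= 3:
        a, b, c = word[-3], word[-2], word[-1]
        return (
            b in _EN_VOWELS
            and c not in _EN_VOWELS
            and c not in "wxY"
            and a not in _EN_VOWELS
        )
    return False


def _en_is_short(word: str, r1: int) -> bool:
    return r1 >= len(word) and _en_short_syllable_at_end(word)


def english_stem(word: str) -> str:
    if len(word) <= 2:
        return word
    if word in _EN_EXCEPTIONS:
        return _EN_EXCEPTIONS[word]
    if word.startswith("'"):
        word = word[1:]
    # mark consonantal y
    chars = list(word)
    if chars and chars[0] == "y":
        chars[0] = "Y"
    for i in range(1, len(chars)):
        if chars[i] == "y" and chars[i - 1] in _EN_VOWELS:
            chars[i] = "Y"
    word = "".join(chars)

    r1, r2 = _en_r1_r2(word)

    # Step 0
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            word = word[: -len(suf)]
            break

    # Step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-3] + ("i" if len(word) > 4 else "ie")
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s"):
        if any(ch in _EN_VOWELS for ch in word[:-2]):
            word = word[:-1]

    if word in _EN_EXCEPTIONS_1A:
        return word

    # Step 1b
    if word.endswith(("eedly", "eed")):
        suf = "eedly" if word.endswith("eedly") else "eed"
        if len(word) - len(suf) >= r1:
            word = word[: -len(suf)] + "ee"
    else:
        for suf in ("ingly", "edly", "ing", "ed"):
            if word.endswith(suf):
                stem = word[: -len(suf)]
                if any(ch in _EN_VOWELS for ch in stem):
                    word = stem
                    if word.endswith(("at", "bl", "iz")):
                        word += "e"
                    elif word.endswith(_EN_DOUBLES):
                        word = word[:-1]
                    elif _en_is_short(word, r1):
                        word += "e"
                break

    # Step 1c
    if (
        len(word) > 2
        and word[-1] in "yY"
        and word[-2] not in _EN_VOWELS
    ):
        word = word[:-1] + "i"

    r1, r2 = _en_r1_r2(word)

    # Step 2
    for suf, repl in _EN_STEP2:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ogi":
                    if word.endswith("logi"):
                        word = word[:-1]
                elif suf == "li":
                    if word[-3:-2] in _EN_LI_END:
                        word = word[:-2]
                else:
                    word = word[: -len(suf)] + repl
            break

    # Step 3
    for suf, repl in _EN_STEP3:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                if suf == "ative":
                    if len(word) - len(suf) >= r2:
                        word = word[: -len(suf)]
                else:
                    word = word[: -len(suf)] + repl
            break

    # Step 4
    for suf in _EN_STEP4:
        if word.endswith(suf):
            if len(word) - len(suf) >= r2:
                if suf == "ion":
                    if word[-4:-3] in ("s", "t"):
                        word = word[:-3]
                else:
                    word = word[: -len(suf)]
            break

    # Step 5
    r1, r2 = _en_r1_r2(word)
    if word.endswith("e"):
        if len(word) - 1 >= r2 or (
            len(word) - 1 >= r1 and not _en_short_syllable_at_end(word[:-1])
        ):
            word = word[:-1]
    elif word.endswith("ll") and len(word) - 1 >= r2:
        word = word[:-1]

    return word.replace("Y", "y")
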