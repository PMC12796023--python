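"""Lexicon extraction of shock etiologies from clinician note text.

The extractor is a literal-term matcher: each of the nine etiologies is
associated with a small list of clinical strings ("Septic Shock",
"cardiac tamponade", ...). Matching is case-insensitive on word
boundaries, with the longest term preferred within an etiology so that
"septic shock" is one mention rather than two. A NegEx-style rule set
then flags mentions preceded by a negation trigger ("no evidence of
septic shock"), and a note becomes a 9-dimensional binary vector with a
1 for each etiology having at least one non-negated mention.

Lexicon and negation rules ship as editable YAML under
``shockagree/data`` and can be swapped at call time.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .etiologies import ETIOLOGIES, N_ETIOLOGIES, etiology_index

__all__ = [
    "Lexicon",
    "NegationRules",
    "NoteMatch",
    "NoteDiagnostics",
    "default_lexicon",
    "default_negation_rules",
    "find_matches",
    "is_negated",
    "vectorize_note",
]

_SHOCK_WORD_RE = re.compile(r"(?<!\w)shock(?!\w)", re.IGNORECASE)
_TOKEN_RE = re.compile(r"\w+")


def _word_bounded(alternatives: list[str]) -> re.Pattern[str]:
    alt = "|".join(re.escape(t) for t in alternatives)
    return re.compile(rf"(?<!\w)(?:{alt})(?!\w)", re.IGNORECASE)


@dataclass(frozen=True)
class Lexicon:
    """Map etiology -> literal term strings, with compiled matchers."""

    terms: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.terms) != set(ETIOLOGIES):
            missing = set(ETIOLOGIES) - set(self.terms)
            extra = set(self.terms) - set(ETIOLOGIES)
            raise ValueError(f"lexicon keys mismatch: missing={missing}, extra={extra}")
        for etiology, term_list in self.terms.items():
            if not term_list:
                raise ValueError(f"lexicon term list for {etiology!r} is empty")
        patterns = {}
        for etiology, term_list in self.terms.items():
            # longest-first so multiword terms win over their substrings
            ordered = sorted(term_list, key=len, reverse=True)
            patterns[etiology] = _word_bounded(list(ordered))
        object.__setattr__(self, "_patterns", patterns)

    def pattern(self, etiology: str) -> re.Pattern[str]:
        return self._patterns[etiology]  # type: ignore[attr-defined]


@dataclass(frozen=True)
class NegationRules:
    """Pre-trigger negation with a token window and scope terminators."""

    triggers: tuple[str, ...]
    pseudo_triggers: tuple[str, ...] = ()
    window: int = 6
    terminator_words: tuple[str, ...] = ("but", "however")

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("negation window must be >= 1")
        trig = sorted(self.triggers, key=len, reverse=True)
        pseudo = sorted(self.pseudo_triggers, key=len, reverse=True)
        object.__setattr__(self, "_trigger_re", _word_bounded(trig))
        object.__setattr__(
            self, "_pseudo_re", _word_bounded(list(pseudo)) if pseudo else None
        )
        words = "|".join(re.escape(w) for w in self.terminator_words)
        term = rf"[.;:?!\n]" + (rf"|(?<!\w)(?:{words})(?!\w)" if words else "")
        object.__setattr__(self, "_terminator_re", re.compile(term, re.IGNORECASE))


@dataclass(frozen=True)
class NoteMatch:
    """One lexicon hit: etiology, literal term, 0-based half-open span."""

    etiology: str
    term: str
    start: int
    end: int
    negated: bool | None = None


@dataclass
class NoteDiagnostics:
    """Per-note extraction audit trail."""

    matches: list[NoteMatch] = field(default_factory=list)
    negated_only: bool = False
    shock_word: bool = False


def _load_yaml(name: str) -> dict:
    with resources.files("shockagree.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


_DEFAULT_LEXICON: Lexicon | None = None
_DEFAULT_RULES: NegationRules | None = None


def default_lexicon() -> Lexicon:
    """The bundled nine-etiology lexicon (cached)."""
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        raw = _load_yaml("lexicon.yaml")
        _DEFAULT_LEXICON = Lexicon({k: tuple(v) for k, v in raw.items()})
    return _DEFAULT_LEXICON


def default_negation_rules() -> NegationRules:
    """The bundled NegEx-style rule set (cached)."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        raw = _load_yaml("negation.yaml")
        _DEFAULT_RULES = NegationRules(
            triggers=tuple(raw["triggers"]),
            pseudo_triggers=tuple(raw.get("pseudo_triggers", ())),
            window=int(raw.get("window", 6)),
            terminator_words=tuple(raw.get("terminator_words", ("but", "however"))),
        )
    return _DEFAULT_RULES


def find_matches(text: str, lexicon: Lexicon | None = None) -> list[NoteMatch]:
    """All word-bounded lexicon occurrences, negation not yet applied.

    Within one etiology the longest term is preferred at a given
    position; occurrences of different etiologies may overlap and are
    all reported. Matches are ordered by start position, then by the
    canonical etiology order.
    """
    if text is None:
        raise ValueError("note text must not be None")
    lexicon = lexicon or default_lexicon()
    out: list[NoteMatch] = []
    for etiology in ETIOLOGIES:
        for m in lexicon.pattern(etiology).finditer(text):
            out.append(NoteMatch(etiology, m.group(0), m.start(), m.end()))
    out.sort(key=lambda nm: (nm.start, etiology_index(nm.etiology)))
    return out


def is_negated(text: str, match: NoteMatch, rules: NegationRules | None = None) -> bool:
    """True iff a negation trigger governs the match.

    A trigger governs when it lies at most ``rules.window`` word tokens
    before the match with no scope terminator (sentence punctuation,
    "but", "however") between, and is not contained in a pseudo-trigger
    ("cannot rule out").
    """
    rules = rules or default_negation_rules()
    pre = text[: match.start]
    last_term = 0
    for tm in rules._terminator_re.finditer(pre):  # type: ignore[attr-defined]
        last_term = tm.end()
    scope = pre[last_term:]
    pseudo_spans: list[tuple[int, int]] = []
    pseudo_re = rules._pseudo_re  # type: ignore[attr-defined]
    if pseudo_re is not None:
        pseudo_spans = [pm.span() for pm in pseudo_re.finditer(scope)]
    for trig in rules._trigger_re.finditer(scope):  # type: ignore[attr-defined]
        if any(s <= trig.start() and trig.end() <= e for s, e in pseudo_spans):
            continue
        gap_tokens = _TOKEN_RE.findall(scope[trig.end():])
        if len(gap_tokens) <= rules.window:
            return True
    return False


def vectorize_note(
    text: str,
    lexicon: Lexicon | None = None,
    rules: NegationRules | None = None,
) -> tuple[np.ndarray, NoteDiagnostics]:
    """Turn note text into a 9-dimensional binary etiology vector.

    Dimension d is 1 iff the note has at least one non-negated mention
    of etiology d. Diagnostics carry the match list (with negation
    flags), a negated-only flag (mentions exist but all are negated),
    and a shock-word flag (the bare word "shock" occurs anywhere, used
    for cohort confirmation).
    """
    lexicon = lexicon or default_lexicon()
    rules = rules or default_negation_rules()
    matches = find_matches(text, lexicon)
    flagged = [
        NoteMatch(m.etiology, m.term, m.start, m.end, is_negated(text, m, rules))
        for m in matches
    ]
    vec = np.zeros(N_ETIOLOGIES, dtype=np.int8)
    for m in flagged:
        if not m.negated:
            vec[etiology_index(m.etiology)] = 1
    diag = NoteDiagnostics(
        matches=flagged,
        negated_only=bool(flagged) and all(m.negated for m in flagged),
        shock_word=bool(_SHOCK_WORD_RE.search(text)),
    )
    return vec, diag
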