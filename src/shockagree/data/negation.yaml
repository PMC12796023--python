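# NegEx-style negation rules for etiology mentions.
#
# A mention is negated when a trigger phrase lies within `window` word
# tokens before it with no scope terminator in between. Pseudo-triggers
# are checked first: a trigger contained inside a pseudo-trigger span
# does not negate.
triggers:
  - "no"
  - "not"
  - "without"
  - "denies"
  - "no evidence of"
  - "without evidence of"
  - "rule out"
  - "ruled out"
  - "negative for"
  - "unlikely"
  - "resolved"
  - "free of"
  - "absence of"
pseudo_triggers:
  - cannot rule out
  - can't rule out
  - cannot be ruled out
  - not ruled out
  - not be ruled out
  - unable to rule out
# Word-token distance a trigger may sit before the mention.
window: 6
# Scope terminators: sentence punctuation plus adversative conjunctions.
terminator_words:
  - but
  - however
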