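# Shock-etiology term lexicon.
#
# Matching is case-insensitive on word boundaries; longest term wins
# within an etiology. "distributive shock" and "shock of unclear
# etiology" are adjudication aliases folded into the undifferentiated
# (unknown) category.
septic:
  - Sepsis
  - Septic
  - Septic Shock
cardiogenic:
  - Cardiac Shock
  - Cardiogenic
  - Cardiogenic Shock
hypovolemic:
  - hypovolemic
  - hypovolemia
  - hypovolemic shock
  - hemorrhage
  - hemorrhagic shock
  - traumatic shock
adrenal:
  - adrenal shock
  - adrenal insufficiency
neurogenic:
  - spinal shock
  - neurogenic shock
undifferentiated:
  - undifferentiated shock
  - shock NOS
  - multifactorial shock
  - distributive shock
  - shock of unclear etiology
obstructive:
  - obstructive shock
  - cardiac tamponade
  - tamponade
  - tension pneumothorax
  - tension pneumo
anaphylactic:
  - anaphylaxis
  - anaphylactic
  - anaphylactic shock
post_procedural:
  - post-procedure shock
  - post-procedural shock
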