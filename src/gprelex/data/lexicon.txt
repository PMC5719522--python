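# Default genotype-phenotype relationship-term lexicon.
# One surface form per line, optionally followed by a tab and a category
# (verb | noun | preposition).  Lookup is case-insensitive and stem-based,
# so inflected surface forms collapse onto one entry per stem.
#
# Verbs encoding a relation between a genetic phenomenon and a disorder,
# plus the two relational prepositions "in" and "for", plus common
# protein-protein-interaction style relation terms that also apply to
# genotype-phenotype relations.
associate	verb
associated	verb
associates	verb
association	noun
correlate	verb
correlated	verb
correlation	noun
cause	verb
causes	verb
caused	verb
link	verb
linked	verb
linkage	noun
relate	verb
related	verb
relationship	noun
affect	verb
affects	verb
influence	verb
influences	verb
induce	verb
induces	verb
confer	verb
confers	verb
predispose	verb
predisposes	verb
contribute	verb
contributes	verb
determine	verb
determines	verb
express	verb
expressed	verb
expression	noun
regulate	verb
regulates	verb
regulation	noun
mediate	verb
mediates	verb
modulate	verb
modulates	verb
involve	verb
involved	verb
interact	verb
interaction	noun
underlie	verb
underlies	verb
confirm	verb
confirmed	verb
susceptibility	noun
responsible	noun
risk	noun
role	noun
in	preposition
for	preposition
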