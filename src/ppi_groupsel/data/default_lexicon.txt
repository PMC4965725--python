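# Default interaction lexicon for ppi-groupsel.
#
# This is a curated STAND-IN for the unpublished 642-word interaction
# keyword list of the original system: it seeds the published examples
# (bind, link, stimulate, interact, induce, regulate, mediate, inhibit)
# with common protein-interaction verbs and nouns. Entries are stemmed at
# load time, so inflected forms are covered automatically. Edit freely;
# pass your own file to Lexicon.load() to replace it.

[keywords]
bind
link
stimulate
interact
induce
regulate
mediate
inhibit
associate
known
activate
phosphorylate
dephosphorylate
suppress
repress
block
enhance
modulate
affect
form
complex
interaction
association
binding
activation
inhibition
regulation
phosphorylation
stimulation
induction
suppression
formation
modulation
attenuate
trigger
recruit
stabilize
destabilize
cleave
catalyze
acetylate
methylate
ubiquitinate
transactivate
cross-link
crosslink
coprecipitate
co-precipitate
immunoprecipitate
coimmunoprecipitate
dimerize
heterodimerize
homodimerize
oligomerize
couple
tether
dock
sequester
antagonize
abolish
abrogate
accelerate
augment
impair
potentiate
prevent
reduce
elevate
upregulate
downregulate
up-regulate
down-regulate
transcribe
express
encode
target
recognize
influence
control
require
depend
cooperate
compete
synergize
correlate
signal
respond
bound
ligation
ligate
attach
anchor
bridge
contact
crosstalk
interplay
effect
receptor

[iverb]
interact
bind
activate
inhibit
stimulate
regulate
induce
associate
phosphorylate
mediate
suppress
repress
block
enhance
modulate
affect
form
recognize
target
cleave
trigger
attenuate
recruit
stabilize
depend
require
couple
dimerize
antagonize
potentiate
upregulate
downregulate

[inoun]
interaction
association
binding
activation
inhibition
regulation
phosphorylation
formation
modulation
stimulation
induction
suppression
recognition
dimerization
ligation
complex
crosstalk
interplay
contact
effect

[negative]
not
incapable
unable

[conjunctive]
although
though
because
as
therefore
hence
since
so
where
when
what
why
how
wherein
whereas
whereby
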