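# French function-word lexicon, one lowercased form per line.
# Articles, prepositions, pronouns, conjunctions, auxiliary forms and
# high-frequency adverbs; clitic forms keep their apostrophe ("j'").
# Fully user-replaceable; order defines feature order.
le
la
les
l'
un
une
des
du
de
d'
au
aux
ce
c'
cet
cette
ces
mon
ma
mes
ton
ta
tes
son
sa
ses
notre
nos
votre
vos
leur
leurs
je
j'
tu
il
elle
on
nous
vous
ils
elles
me
m'
te
t'
se
s'
en
y
moi
toi
lui
eux
soi
qui
que
qu'
quoi
dont
où
ne
n'
pas
plus
moins
très
bien
mal
aussi
alors
donc
puis
ensuite
enfin
encore
déjà
toujours
jamais
souvent
ici
là
et
ou
mais
ni
or
car
si
comme
quand
lorsque
parce
puisque
quoique
à
dans
par
pour
sans
sous
sur
vers
avec
chez
entre
contre
depuis
pendant
avant
après
être
suis
es
est
sommes
êtes
sont
était
étais
étaient
été
sera
serait
avoir
ai
as
a
avons
avez
ont
avait
avais
avaient
eu
aura
aurait
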