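# Frozen fixture subword vocabulary for greedy longest-match segmentation.
# Single characters guarantee coverage; multi-character pieces make the
# segmentation non-trivial. Real wordpiece tokenizers plug in behind the
# same contract.
a
b
c
d
e
f
g
h
i
j
k
l
m
n
o
p
q
r
s
t
u
v
w
x
y
z
'
the
and
ing
ion
tion
ation
er
est
ed
ly
al
en
an
in
on
at
it
is
or
ar
re
le
st
ch
sh
th
wh
oo
ee
ea
ou
ow
boy
girl
cook
coo
kie
cookie
jar
water
moth
run
fall
sink
dish
stool
over
flow
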