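# Frozen fixture subword vocabulary for Greek, greedy longest-match.
# Greek alphabet plus a handful of frequent digraphs and endings; Latin
# letters included so synthetic lexica segment too.
α
β
γ
δ
ε
ζ
η
θ
ι
κ
λ
μ
ν
ξ
ο
π
ρ
σ
ς
τ
υ
φ
χ
ψ
ω
ου
αι
ει
οι
μπ
ντ
γκ
τσ
τζ
ος
ης
ες
ων
ει
ια
εια
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
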