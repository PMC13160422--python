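# mtmolgen SMILES vocabulary, version 1.
# Exactly 48 tokens: 4 specials + 44 chemistry tokens covering the organic
# subset, halogens, ring-bond digits, branching, bond orders and the common
# charged / bracket atoms of drug-like SMILES.
<pad>
<bos>
<eos>
<unk>
C
N
O
S
P
F
I
B
Cl
Br
c
n
o
s
p
1
2
3
4
5
6
7
8
%
=
#
-
/
\
(
)
[nH]
[N+]
[N-]
[O-]
[n+]
[NH+]
[NH2+]
[NH3+]
[C@H]
[C@@H]
[S+]
[s+]
[P+]
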