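format-version: 1.2
ontology: toy

[Term]
id: R
name: root

[Term]
id: A
name: branch a
is_a: R

[Term]
id: B
name: branch b
is_a: R

[Term]
id: C
name: leaf c
is_a: A

[Term]
id: D
name: leaf d
is_a: A

[Term]
id: E
name: leaf e
is_a: A
is_a: B
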