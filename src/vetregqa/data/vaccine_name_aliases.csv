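alias,canonical
aquavac relera,Aquavac Relera Bath
alpha erm salar vet bath,Alpha Erm Salar Bath
alphaject micro 6,Alpha Ject Micro 6
alphaject 3000,Alpha Ject 3000
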