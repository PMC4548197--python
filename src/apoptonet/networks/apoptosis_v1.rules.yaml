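name: apoptosis_v1
order:
- CASP8
- CASP9
- CASP3
- BID
- BAX
- CYTC
- SMAC
- APAF
- IAP
- AKT
- BAD
- BCL2
- IKK
- IKB
- NFKB
- CFLIP
- MDM2
- P53
- DNADAM
- FASL
- GF
inputs:
- FASL
- GF
self_degrading:
- AKT
- APAF
- BAD
- BID
- CFLIP
- CYTC
- DNADAM
- IKB
- IKK
- NFKB
- SMAC
constitutive:
- BAD
- IKB
- NFKB
gates:
- watched: DNADAM
  threshold: 3
  mode: sustained
  targets:
  - P53
- watched: CASP3
  threshold: 2
  mode: pulse
  targets:
  - IAP
- watched: P53
  threshold: 2
  mode: pulse
  targets:
  - BAX
- watched: P53
  threshold: 2
  mode: sustained
  targets:
  - BCL2
  - MDM2
  - P53
display_names:
  CYTC: CYT-C
  IKB: IkB
  NFKB: NF-kB
  CFLIP: cFLIP
  P53: p53
  DNADAM: DNA-damage
  FASL: FasL
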