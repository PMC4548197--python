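name: hsp70_overlay
order:
- HSP70
inputs:
- HSP70
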