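# Default candidate model set of the neuropathic-pain case study:
# three Emax and two sigmoid-Emax standardized shapes.
- {label: Emax1, family: emax, params: {ed50: 0.05}}
- {label: Emax2, family: emax, params: {ed50: 0.2}}
- {label: Emax3, family: emax, params: {ed50: 0.7}}
- {label: sigEmax1, family: sigEmax, params: {ed50: 0.25, h: 3}}
- {label: sigEmax2, family: sigEmax, params: {ed50: 0.6, h: 2}}
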