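# Suggested optimized b-value schemes for brain IVIM (b in s/mm^2, one
# averages entry per b value), for 3/6/12-minute scan budgets, as published
# for grey matter (gm) and white matter (wm): fixed-base f-optimized sets,
# GLM-selected D*- and D-optimized sets, and CRLB-optimized sets targeting
# f, D and D* jointly.
- {label: gm-f-3min, strategy: manual, bvalues: [0, 200, 900], averages: [5, 5, 5]}
- {label: gm-f-6min, strategy: manual, bvalues: [0, 200, 900], averages: [10, 10, 10]}
- {label: gm-f-12min, strategy: manual, bvalues: [0, 200, 900], averages: [20, 20, 20]}
- {label: gm-dstar-3min, strategy: manual, bvalues: [0, 200, 800, 900], averages: [4, 4, 4, 4]}
- {label: gm-dstar-6min, strategy: manual, bvalues: [0, 200, 800, 900], averages: [8, 8, 8, 8]}
- {label: gm-dstar-12min, strategy: manual, bvalues: [0, 200, 800, 900], averages: [16, 16, 16, 16]}
- {label: gm-d-3min, strategy: manual, bvalues: [0, 10, 20, 40, 80, 140, 200, 900], averages: [2, 2, 2, 2, 2, 2, 2, 2]}
- {label: gm-d-6min, strategy: manual, bvalues: [0, 10, 20, 40, 80, 140, 200, 900], averages: [4, 4, 4, 4, 4, 4, 4, 4]}
- {label: gm-d-12min, strategy: manual, bvalues: [0, 10, 20, 40, 80, 140, 200, 900], averages: [8, 8, 8, 8, 8, 8, 8, 8]}
- {label: gm-crlb-3min, strategy: manual, bvalues: [0, 20, 110, 140, 400, 500, 600], averages: [2, 3, 2, 2, 1, 4, 2]}
- {label: gm-crlb-6min, strategy: manual, bvalues: [0, 20, 140, 400, 500, 600, 700, 800, 900], averages: [2, 5, 6, 9, 1, 5, 1, 1, 2]}
- {label: gm-crlb-12min, strategy: manual, bvalues: [0, 20, 140, 300, 500, 700, 800, 900], averages: [7, 4, 19, 9, 19, 1, 4, 1]}
- {label: wm-f-3min, strategy: manual, bvalues: [0, 200, 900], averages: [5, 5, 5]}
- {label: wm-f-6min, strategy: manual, bvalues: [0, 200, 900], averages: [10, 10, 10]}
- {label: wm-f-12min, strategy: manual, bvalues: [0, 200, 900], averages: [20, 20, 20]}
- {label: wm-dstar-3min, strategy: manual, bvalues: [0, 200, 800, 900], averages: [4, 4, 4, 4]}
- {label: wm-dstar-6min, strategy: manual, bvalues: [0, 200, 800, 900], averages: [8, 8, 8, 8]}
- {label: wm-dstar-12min, strategy: manual, bvalues: [0, 200, 800, 900], averages: [16, 16, 16, 16]}
- {label: wm-d-3min, strategy: manual, bvalues: [0, 10, 20, 40, 80, 200, 300, 900], averages: [2, 2, 2, 2, 2, 2, 2, 2]}
- {label: wm-d-6min, strategy: manual, bvalues: [0, 10, 20, 80, 200, 300, 900], averages: [4, 4, 4, 4, 4, 4, 4]}
- {label: wm-d-12min, strategy: manual, bvalues: [0, 10, 20, 40, 80, 200, 300, 900], averages: [8, 8, 8, 8, 8, 8, 8, 8]}
- {label: wm-crlb-3min, strategy: manual, bvalues: [0, 20, 110, 140, 400, 600, 700], averages: [4, 4, 2, 2, 1, 2, 1]}
- {label: wm-crlb-6min, strategy: manual, bvalues: [0, 20, 40, 80, 110, 140, 170, 500, 600], averages: [5, 9, 1, 1, 9, 1, 2, 3, 1]}
- {label: wm-crlb-12min, strategy: manual, bvalues: [0, 40, 140, 170, 300, 400, 500, 600, 800], averages: [2, 8, 13, 6, 1, 1, 10, 20, 3]}
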