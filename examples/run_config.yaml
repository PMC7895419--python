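# One configured run for the CLI:  pggchoice run --config examples/run_config.yaml
n: 2
r: [4.4, 2.8]
g: 10
c: 1.0
pi0: 1.0
nu_s: 1.0e-3
nu_g: 1.0e-3
engine: replicator    # or: abm (then set N, a multiple of g)
T: 4000
init: homogeneous     # homogeneous | favorable | unfavorable | random
seed: 0
outdir: out/fig1_point
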