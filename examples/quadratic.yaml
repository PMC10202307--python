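problem: quadratic
method: L1+Ada.+MAD
n_particles: 1000
budget: 20000
max_generations: 8
seed: 1
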