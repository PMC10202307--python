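# Demonstration problem with the sensitivity-weighted adaptive distance and
# augmented regression targets (theta^1..theta^4).
problem: demo
method: L1+Ada.+MAD+SensiLR+P4
n_particles: 500
budget: 50000
max_generations: 50
seed: 1
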