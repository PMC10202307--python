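# Large Lotka-Volterra Markov jump process at reduced budget; observed data
# are one exact Gillespie realization at the ground truth (0.5, 0.0025, 0.3).
problem: T6
method: L1+Ada.+MAD
n_particles: 100
budget: 5000
max_generations: 60
seed: 1
data_seed: 101
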