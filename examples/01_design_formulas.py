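"""Size a training population from observed LD.

Chains the three design formulas: Sved's drift relation gives the
effective population size from mean adjacent-marker LD, Me converts that
to the effective number of independent chromosome segments, and the
expected-accuracy equation is inverted for the training-set size that
reaches a target accuracy.
"""

from polygs import effective_segments, expected_accuracy, required_training_n, sved_ne

r2_adjacent = 0.1      # mean LD between adjacent markers
c = 0.003              # adjacent-marker spacing, Morgans
L = 8.0                # genome length, Morgans (7 chromosomes)
h2 = 0.4               # trait heritability
target_r2 = 0.5        # wanted squared prediction accuracy

ne = sved_ne(r2_adjacent, c)
me = effective_segments(ne, L)
n = required_training_n(target_r2, h2, me)

print(f"effective population size Ne     = {ne:.1f}")
print(f"effective genome segments Me     = {me:.1f}")
print(f"required training individuals N  = {n:.1f}")
print(f"sanity: accuracy at that N       = {expected_accuracy(n, h2, me):.4f}")
# Ne ~ 750 segments the genome into ~1190 effective pieces; reaching
# r^2 = 0.5 for a h2 = 0.4 trait with unrelated individuals then needs
# ~3000 phenotyped-and-genotyped plants.
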