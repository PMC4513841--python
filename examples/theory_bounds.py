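"""Theoretical maximum stringency of an 811 bp inducible-toxin cassette.

Propagates the E. coli genomic mutation-rate interval down to the rate at
which escape mutants (cassette-inactivating point mutations plus large
deletions) can arise, and places a measured escape rate on that scale.
"""
from negselect.theory import DEFAULT_INPUTS, classify_observed, theory_chain

chain = theory_chain(DEFAULT_INPUTS)
for stage, interval in chain.items():
    print(f"{stage:15s}: {interval.low:.3g} .. {interval.high:.3g}  per generation")

observed = 1.42e-8  # fluctuation-test escape rate of the cassette
verdict = classify_observed(observed, chain["inactivation"])
print(f"\nmeasured escape rate {observed:.3g} is '{verdict}' the inactivation interval")
# 'within' means the cassette performs about as well as replication
# fidelity allows: most escapes are unavoidable inactivating mutations.
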