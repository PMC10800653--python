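"""The frequency-accuracy link and the 1 - r latency proxy.

Under frequency-informed learning, correctness rises with log frequency
(a positive logistic slope); under the frequency-free endstate there is no
detectable relationship. The per-word 1 - r measure (one minus the target
correlation) is the model's proxy for lexical decision latency: small for
well-learned words, large for poorly learned ones.
"""

import numpy as np
import statsmodels.api as sm

import lexlearn as ll

cfg = ll.GeneratorConfig(seed=2)
lexicon = ll.generate_lexicon(cfg)
C = ll.build_cue_matrix(lexicon, n=2)
S, _ = ll.generate_semantics(lexicon, C, cfg)
f = lexicon.frequencies

el = ll.solve_linear_mapping(C, S)
fil = ll.solve_frequency_informed(C, S, f)

X = sm.add_constant(np.log(f + 1.0))
for name, mapping in [("EL", el), ("FIL", fil)]:
    _, flags = ll.accuracy_at_k(ll.predict(C, mapping), S, 1)
    fit = sm.GLM(flags.astype(float), X,
                 family=sm.families.Binomial()).fit()
    print(f"{name}: logistic slope of correct@1 on log(f+1) = "
          f"{fit.params[1]:+.3f}  (p = {fit.pvalues[1]:.3g})")
print("-> only the frequency-informed mapping knows which words are frequent\n")

table = ll.evaluate_mapping(C, S, fil, lexicon, ks=(1, 10))
lo = table[table.frequency <= 2]["one_minus_r"].median()
hi = table[table.frequency >= 50]["one_minus_r"].median()
print(f"median 1-r (latency proxy), rare words (f<=2):     {lo:.3f}")
print(f"median 1-r (latency proxy), frequent words (f>=50): {hi:.3f}")
print("-> frequent words sit closer to their semantic targets, "
      "predicting faster decisions")
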