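"""Cohen's kappa: from rating vectors, and from published marginal counts.

Demonstrates both kappa paths — a full cross-tabulation of two simulated
readers, and the marginals-plus-discrepancies path that reconstructs the
aggregated inter-method kappas of the modelled 19-patient cohort.
"""

from bonetrack import (
    RatingVector,
    ReaderModel,
    contingency,
    discrepancy_count,
    kappa_from_table,
    reproduce_agreement_table,
    simulate_reader,
)

# two noisy readers looking at the same 52 true lesion changes
truth = ["progressive"] * 13 + ["stable"] * 13 + ["regressive"] * 26
confusion = ((0.8, 0.15, 0.05), (0.1, 0.8, 0.1), (0.05, 0.15, 0.8))
ids = tuple(f"L{i:02d}" for i in range(len(truth)))
a = RatingVector(ids, tuple(simulate_reader(truth, ReaderModel(confusion, seed=1))), "reader A")
b = RatingVector(ids, tuple(simulate_reader(truth, ReaderModel(confusion, seed=2))), "reader B")

res = kappa_from_table(contingency(a, b))
n_disc, frac = discrepancy_count(a, b)
print(f"simulated readers: kappa = {res.kappa:.2f} ({res.label}), "
      f"discrepant {n_disc}/{len(a)} = {100 * frac:.1f} %")
print()

# reconstruction of the cohort's aggregated inter-method agreement
table = reproduce_agreement_table()
print(table[["comparison", "n", "p0", "pe", "kappa", "label"]].to_string(index=False))
# kappa corrects the raw agreement p0 for the chance agreement pe implied by
# each method's marginal category frequencies.
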