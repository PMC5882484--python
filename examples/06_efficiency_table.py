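"""Efficiency comparison of the three nonconformity measures.

Median prediction interval width (MPI) per confidence level, on strongly
heteroscedastic data where a per-compound error model should pay off:
abs_diff gives every compound the same width, while normalized and
log-normalized adapt widths to difficulty.  The adaptive measures win
over certain confidence ranges rather than everywhere — compare the
columns.
"""

import confomer as cf

X, y = cf.make_vector_dataset(cf.strongly_heteroscedastic_spec(n=3000,
                                                               seed=42))
train, test = (X[:1500], y[:1500]), (X[1500:], y[1500:])

ccps = {}
for kind in ("abs_diff", "normalized", "log_normalized"):
    beta = 1.0 if kind == "log_normalized" else 0.0
    ccps[kind] = cf.ccp_fit(
        train, k=10, params=cf.SvrParams(cost=1.0, epsilon=1e-3),
        ncm=cf.NonconformityConfig(kind=kind, beta=beta),
        seed=42, n_features=200)


def predict_fn(variant, conf):
    return cf.ccp_predict_many(ccps[variant], test[0], conf)


mpi, cov = cf.efficiency_report(predict_fn, test[1],
                                ["abs_diff", "normalized",
                                 "log_normalized"],
                                [0.5, 0.7, 0.8, 0.9])
print("median prediction interval width (rows: measure):")
print(mpi.round(3))
print("\nempirical coverage per cell (validity audit):")
print(cov.round(3))
print("\nsmaller MPI at the same (valid) coverage = higher efficiency; "
      "\nthe adaptive measures are tightest in the mid-to-high range.")
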