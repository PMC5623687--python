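"""Train the LDA classifier and report fivefold cross-validation accuracy.

The shared-covariance Gaussian discriminant is fitted on the per-class
offline feature matrix; stratified fivefold cross-validation yields the
offline error rate and the 7x7 confusion matrix (row-normalized percent,
per-class accuracy on the diagonal).
"""

import myolock as ml

recording = ml.generate_session(ml.offline_protocol(), ml.GeneratorParams(seed=1))
fm = ml.per_class_feature_matrix(recording)
error, confusion = ml.crossval(fm, folds=5, seed=0)

print(f"fivefold CV error rate: {100 * error:.2f}%  "
      f"(accuracy {100 * confusion.accuracy:.2f}%)")
print(confusion.to_text())

# The diagonal holds each motion class's accuracy; off-diagonal cells show
# which classes are confused. Rest (NM) confusions come from weak trials.
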