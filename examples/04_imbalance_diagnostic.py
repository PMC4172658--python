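"""Why G-mean: a classifier that writes off a rare class still scores
high accuracy, but its G-mean collapses to zero.

Uses the imbalanced benchmark (classes of 60/40/20/10/6 samples) and a
degenerate classifier that predicts the majority class for every sample of
the smallest class.
"""

from fprf import accuracy, confusion_matrix, f_score, g_mean, imbalanced_benchmark

ds, _ = imbalanced_benchmark()
sizes = {c: len(i) for c, i in ds.class_indices().items()}
smallest = min(sizes, key=sizes.get)
largest = max(sizes, key=sizes.get)

y_true = list(ds.labels)
y_pred = [largest if c == smallest else c for c in y_true]
cm = confusion_matrix(y_true, y_pred, ds.classes)

print(f"class sizes: {sizes}")
print(f"degenerate classifier ignores {smallest!r}")
print(f"Acc = {accuracy(cm):.3f}   F = {f_score(cm):.3f}   G = {g_mean(cm):.3f}")
# Accuracy barely notices the 6 misclassified samples; the zero recall on
# the smallest class drives G to 0 - the gap is the imbalance alarm.
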