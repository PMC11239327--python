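"""The symmetrized F1 similarity between two bicluster collections.

Rectangles are sample-set x feature-set pairs.  The one-sided score
S(M1, M2) averages each rectangle of M1's best F1 match in M2; the reported
measure is the average of both directions, 1.0 iff the collections coincide.
"""

from hmmbiclust import Bicluster, f1_pair, f1_symmetric, similarity

truth = [
    Bicluster(samples=range(0, 5), features=range(0, 10)),
    Bicluster(samples=range(5, 10), features=range(10, 20)),
]
estimate = [
    Bicluster(samples=range(0, 5), features=range(0, 10)),    # exact match
    Bicluster(samples=range(5, 10), features=range(10, 15)),  # half the features
]

print(f"pairwise F1 of the exact match:   {f1_pair(estimate[0], truth[0]):.3f}")
print(f"pairwise F1 of the partial match: {f1_pair(estimate[1], truth[1]):.3f}")
print(f"S(estimate, truth) = {similarity(estimate, truth):.3f}")
print(f"S(truth, estimate) = {similarity(truth, estimate):.3f}")
print(f"symmetrized F1     = {f1_symmetric(estimate, truth):.3f}")
print("the partial rectangle (25 of 50 cells shared, sizes 25 and 50) "
      "scores 2*25/(25+50) = 0.667")
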