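"""Select the number of sample clusters with a DIC scan.

Fits the model once per candidate K and prints the DIC curve.  Lower is
better; the curve drops steeply until the true K and flattens beyond it,
and K values whose MAP partition contains near-empty clusters should not
be selected.  Here the truth is K=2.
"""

from hmmbiclust import Hyperparams, dic_scan, simulate

M, truth = simulate(n=80, K=2, p=300, sigma2=1.0, seed=4)
results = dic_scan(M, Hyperparams(K=1), K_grid=[1, 2, 3],
                   iters=600, burn_in=300, seed=9)

print(" K      DIC   empty-cluster draws   smallest MAP cluster")
for r in results:
    print(f"{r.K:2d} {r.dic:9.1f}   {r.n_empty_cluster_draws:7d} "
          f"             {r.min_map_cluster_size:5d}")
drop = results[0].dic - results[1].dic
tail = abs(results[2].dic - results[1].dic)
print(f"\ndrop into K=2: {drop:.1f}; change beyond K=2: {tail:.1f} "
      f"(flat). Elbow rule: pick the smallest K on the flat part, K=2; "
      f"larger K also starts producing tiny clusters.")
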