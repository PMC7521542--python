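"""Topology of an estimated network: small-world indices, efficiency,
modularity and hubs.

Estimates an SGR network for one synthetic subject, binarizes it at 20%
edge density, and prints the graph-theory metric bundle against 100
degree-preserving null networks.
"""

from sgrnet import SolverConfig, estimate, normalize_weights, symmetrize
from sgrnet.simulate import make_ground_truth, simulate_bold
from sgrnet.topology import hub_nodes, prepare_network, topology_report

truth = make_ground_truth(n_rois=30, n_modules=5, seed=2)
ts = simulate_bold(truth, t_volumes=150, seed=3)
res = estimate(ts, SolverConfig(lam=0.3, beta=2.0))
w = normalize_weights(symmetrize(res.w))

net = prepare_network(w, mode="binary", density=0.2)
rep = topology_report(net, n_null=100, seed=4)

print(f"clustering coefficient Cp   {rep.cp:.4f}")
print(f"characteristic path Lp      {rep.lp:.4f}")
print(f"global efficiency           {rep.e_global:.4f}")
print(f"modularity Q                {rep.q:.4f}")
print(f"gamma (Cp/Cp_rand)          {rep.gamma_norm:.4f}")
print(f"lambda (Lp/Lp_rand)         {rep.lambda_norm:.4f}")
print(f"sigma (gamma/lambda)        {rep.sigma:.4f}")
# sigma above 1 marks small-world organization: the modular ground truth
# leaves the thresholded network slightly more clustered than its
# degree-matched rewired nulls at comparable path length

hubs = hub_nodes(net, method="top_k", k=5)
print("\ntop-5 hubs by degree:")
for idx, label, strength in hubs.hubs:
    print(f"  {label:>8}  degree {strength:.0f}")
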