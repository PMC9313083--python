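"""Build a coexpression network over planted modules and intersect two of them.

Two 10-gene modules are planted at within-module correlation 0.9. The network
threshold τ* is selected where the observed clustering coefficient most
exceeds the random (Erdős–Rényi density) expectation; common connectivity
patterns (CCPs) between two datasets' networks are the shared-edge components.
"""

from degnet import (
    PlantedModule,
    SimulationConfig,
    coexpression_network,
    find_ccps,
    simulate_collection,
)

genes = tuple(f"G{i:02d}" for i in range(1, 21))
cfg = SimulationConfig(
    seed=3, n_datasets={"LC": 2}, samples_per_arm=20, n_genes=40,
    modules=(PlantedModule("M1", genes[:10], correlation=0.9),
             PlantedModule("M2", genes[10:], correlation=0.9)))
(ds_a, ds_b), truth = simulate_collection(cfg)

net_a = coexpression_network(ds_a, list(genes))
net_b = coexpression_network(ds_b, list(genes))
print(f"network A: tau*={net_a.tau_star:.2f}, "
      f"{net_a.graph.number_of_edges()} edges")
print(f"network B: tau*={net_b.tau_star:.2f}, "
      f"{net_b.graph.number_of_edges()} edges")
# tau* sits just above the background correlation noise, keeping the two
# planted 45-edge modules and little else.

for rank, ccp in enumerate(find_ccps(net_a, net_b), start=1):
    module = truth.loc[ccp[0], "module_id"]
    print(f"CCP {rank}: {len(ccp)} nodes "
          f"(planted module {module}): {','.join(ccp)}")
# Each CCP is a connected set of genes coexpressed in BOTH datasets — here
# exactly the two planted modules.
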