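"""Perfect-proxy lookup (r² = 1) and greedy LD pruning (r² < 0.2).

Each simulated LD block contains an exact copy (or allele-flipped copy)
of its anchor SNP, so a perfect-proxy query returns that partner; the
greedy prune then keeps one representative per correlated group,
best p-value first.
"""

from pleioscan import SimulationConfig, compute_r2, find_proxies, prune_independent
from pleioscan.simulate import simulate_reference_panel

cfg = SimulationConfig(seed=4, n_blocks=6, snps_per_block=3,
                       n_panel_samples=500, within_block_r2=0.8,
                       n_planted_pleiotropic=1)
panel = simulate_reference_panel(cfg)
plan = panel.sim_params["plan"]
anchors = list(plan.loc[plan["role"] == "anchor", "rsid"])

proxies, unresolved = find_proxies(panel, anchors, r2_min=1.0, window_bp=500_000)
for rsid in anchors[:3]:
    print(f"{rsid}: perfect proxies -> {proxies[rsid].proxy_rsids}")

# prune a mixed candidate list: anchor + its perfect proxy + a weaker block member
block0 = plan[plan["block"] == 0]
cands = [(block0.iloc[0]["rsid"], 1e-12),   # anchor, best p
         (block0.iloc[1]["rsid"], 1e-10),   # perfect proxy, r2 = 1 with anchor
         (block0.iloc[2]["rsid"], 1e-8)]    # member, r2 ~ 0.8 with anchor
result = prune_independent(cands, panel, r2_max=0.2)
print("candidates:", [c[0] for c in cands])
print("independent after pruning:", result.kept)
r2 = compute_r2(panel, cands[0][0], cands[1][0])
print(f"r2(anchor, proxy) = {r2:.3f} -> proxy pruned away")
# Only the anchor survives: both partners exceed r2 = 0.2 with it.
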