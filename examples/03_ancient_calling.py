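"""Detect catalog variants in simulated ancient reads, with and without the
deamination filter.

Ancient DNA accumulates C->T mismatches near 5' read ends (G->A near 3'),
which mimic real C>T variant support. The example estimates the damage
profile from the reads themselves, then shows how the read-end window filter
(k = 3) separates damage from real carriers.
"""

import numpy as np

import paleopv as pv

rng = np.random.default_rng(11)
seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))

# a small catalog away from coverage edges; S0 and S2 are planted carriers
catalog, _, _ = pv.plant_variants({"human": seq}, 8, seed=12, region=(60, 2940))
labels = [v.label for v in catalog]
samples = [pv.AncientSample("S0", 2500.0, "Lake Baikal"),
           pv.AncientSample("S1", 7500.0, "Anatolia"),
           pv.AncientSample("S2", 11000.0, "Levant")]
truth = {"S0": labels[:2], "S1": [], "S2": labels[2:4]}

damage = pv.DamageModel(d0=0.3, lam=0.5, k=3)   # heavy, untreated library
pileup, _ = pv.simulate_cohort(seq, catalog, truth, samples, coverage=12,
                               read_len=60, damage=damage, seed=13)

# 1. estimate the damage profile from a scan of the reference's C sites
c_sites = [i + 1 for i, b in enumerate(seq) if b == "C"]
damage_scan = pv.simulate_ancient_reads(seq, {}, coverage=30, read_len=60,
                                        damage=damage, seed=14, sites=c_sites,
                                        sample_id="S0")
model = pv.estimate_damage_profile(damage_scan, max_pos=15)
print(f"fitted damage      : d0={model.d0:.3f}, lambda={model.lam:.3f} "
      "(terminal C->T rate and per-base decay)")

# 2. carrier calls with the read-end damage filter
meta = {s.sample_id: s for s in samples}
calls = pv.scan_samples(catalog, pileup, meta, k=3)
present = calls[calls["status"] == "present"]
print(f"\ncarrier calls (k=3): {len(present)} present")
for row in present.itertuples():
    print(f"  {row.sample_id} {row.variant:18s} depth={row.depth} "
          f"alt={row.alt_total} clean={row.alt_clean} date={row.date_bp} BP")
print("planted truth      :", {k: v for k, v in truth.items() if v})

# 3. timing of the called carriers
timing = pv.timing_summary(present)
print(f"\ntiming bins (BP)   : {timing['bins']}  ({timing['percent']})")
# damage_only flags mark sites whose entire alt support sat in the
# deamination window — the calls the filter saved us from.
print("damage-only sites  :", int(calls["damage_only"].sum()))
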