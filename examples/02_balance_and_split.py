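"""Balance a raw target-pair dataset and draw stratified train/test trials.

Reproduces the balancing arithmetic for raw class counts (150, 200, 110):
the limiting count is the 110 dual-target compounds, so both single-target
classes are subsampled to 55 and the balanced dataset holds 220 compounds,
half DT and half ST.
"""

from promisig import LibraryConfig, balance_dataset, generate_library, make_trials

libs = generate_library(
    LibraryConfig(n_pairs=2, n_st_a=150, n_st_b=200, n_dt=110, seed=1)
)
lib = libs[0]
print(f"raw counts:      ST-A={len(lib.st_a)}, ST-B={len(lib.st_b)}, "
      f"DT={len(lib.dt)}")

dataset = balance_dataset(lib.pair, lib.st_a, lib.st_b, lib.dt, seed=1)
print(f"balanced counts: ST-A={len(dataset.st_a)}, ST-B={len(dataset.st_b)}, "
      f"DT={len(dataset.dt)}  (total {dataset.n})")
print(f"class prior:     {len(dataset.dt)} DT vs "
      f"{len(dataset.st_a) + len(dataset.st_b)} ST -> balanced accuracy is the "
      "honest headline measure")

trials = make_trials(dataset, n_trials=10, master_seed=1)
t0 = trials[0]
print(f"trial 0: {len(t0.train)} train / {len(t0.test)} test compounds")
overlap = len(trials[0].train & trials[1].train)
print(f"trials differ: trials 0 and 1 share {overlap}/{len(t0.train)} "
      "training compounds")
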