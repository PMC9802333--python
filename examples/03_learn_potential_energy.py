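"""Learn the pairwise potential and differentiate it into forces.

In potential mode the edge network outputs one scalar per directed edge
and the node operator takes the negative derivative of the summed incoming
messages with respect to the receiver position (then divides by mass).
Only potential *increments* are identifiable — an additive constant in the
potential changes nothing observable — so the error metric compares
increments relative to the initial configuration.
"""

from newtongn.experiments import ExperimentConfig, run_experiment

config = ExperimentConfig(
    law="spring",
    mode="potential",
    n_steps=1000,
    max_epochs=80,
    hidden_units=128,
    hidden_layers=4,
    seed=0,
)
report = run_experiment(config)
print("test-split report (potential mode):")
print(f"  MAE_acc    = {report.mae_acc:.4f}   (supervised target)")
print(f"  MAE_dep    = {report.mae_dep:.4f}   (potential increments vs truth)")
print(f"  MAE_ef     = {report.mae_ef:.4f}   (forces = -dP/dr, never supervised)")
print(f"  MAE_symm_P = {report.mae_symm_p:.4f}   (P_ij vs P_ji symmetry)")
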