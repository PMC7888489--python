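"""Decompose the information flow into one spin from a pair of drivers.

Simulates Glauber dynamics on a small heterogeneous network near its
critical temperature, estimates the lagged joint distribution of one target
spin and two source spins, and splits the joint transfer entropy into
unique, redundant and synergistic parts with both closures (MMI and the
Bertschinger-style constrained minimization).
"""

from connsyn import (
    estimate_lagged_joint,
    generate_heterogeneous_connectome,
    pid_bertschinger,
    pid_from_distribution,
    simulate_at_beta,
)

net = generate_heterogeneous_connectome(20, seed=2)
series = simulate_at_beta(
    net, beta=0.9, discard=1000, collect=50_000, seed=9,
    normalization="mean_strength",
)

target, sources = 4, (7, 12)
dist = estimate_lagged_joint(series, target, sources)

for result in (pid_from_distribution(dist, "MMI"), pid_bertschinger(dist)):
    print(f"\n{result.method} decomposition of T({sources} -> {target}):")
    print(f"  joint TE     = {result.T_joint:.5f} bits")
    print(f"  unique({sources[0]})    = {result.U_j:.5f}")
    print(f"  unique({sources[1]})   = {result.U_k:.5f}")
    print(f"  redundancy   = {result.R:.5f}")
    print(f"  synergy      = {result.S:.5f}")
print(
    "\nSynergy is the part of the information about the target's next state"
    "\nthat only the joint state of both sources carries; the two closures"
    "\nagree closely on spin data."
)
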