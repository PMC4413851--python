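# Derivation of the weight updates

## Forward pass

Per trial, with target `v`, posture `p`, projection `P` (2 × N_M):

```
u = J_v v + J_p p − θ           pre-activations, length N
z = act(u)                      rectified nonlinearity, z ≥ 0
A = z / ‖z‖                     normalized activity, AᵀA = 1 (zero if z = 0)
s = W A                         muscle drive, length N_M
M = [s]_+                       rectified muscle activity
x = P M                         executed movement
e = v − x                       movement error
C = ½‖e‖² + (λ/2)‖M‖²           trial cost
```

## Neuron-to-muscle update (ΔW)

`∂C/∂M = −Pᵀe + λM` and `∂M_m/∂s_m` is 1 where the muscle is active and 0
where its drive is negative. Writing `P_+` for `P` with inactive-muscle
columns zeroed,

```
∂C/∂W = −(P_+ᵀ e − λ M) Aᵀ
ΔW    = η (P_+ᵀ e − λ M) Aᵀ
```

At the rectification kink (`s_m = 0` exactly) the subderivative is the
interval [0, 1]; the implementation picks 1. This matters: with the
zero-initialized `W` every drive starts exactly at the kink, and picking
subgradient 0 would zero every column of `P_+` and freeze learning at the
initial weights forever. Picking 1 lets the first update for each condition
push the aligned muscles positive, after which the mask behaves as the
ordinary gradient. Away from the kink the two conventions coincide, which is
what the finite-difference oracle tests check (they reject near-kink
instances).

A consequence of the masked gradient worth knowing about: if, for some
input condition, every muscle drive is driven strictly negative, that
condition produces no further updates from its own trials and can only be
revived through weight changes driven by other conditions that share active
neurons. Densely coded networks (low θ, heavily overlapping activity) enter
this state frequently, which is part of why they plateau at high error;
sparse networks rarely do.

## Sensory-weight update (ΔJ), comparison networks

For the rectified-tanh networks the same cost is differentiated through the
activation and the normalization. With `g = ∂C/∂s = (−Pᵀe + λM) ⊙ 1[s ≥ 0]`:

```
∂C/∂A = Wᵀ g
∂C/∂z = (I − A Aᵀ) (∂C/∂A) / ‖z‖      (normalization projects out the radial part)
∂C/∂u = ∂C/∂z ⊙ β(1 − tanh²(βu)) ⊙ 1[tanh(βu) > 0]
∂C/∂J_v = (∂C/∂u) vᵀ,   ∂C/∂J_p = (∂C/∂u) pᵀ
ΔJ_v = −η ∂C/∂J_v,      ΔJ_p = −η ∂C/∂J_p
```

Both updates are verified against central finite differences of the trial
cost on randomized kink-free instances (relative tolerance 1e−5 for ΔW,
1e−4 for ΔJ).
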