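# Permeability tensors and coupling matrix of the manufactured-solution
# verification case on the unit cube.  The structure mirrors the brain
# model at O(1) scale: rank-1 descending-vessel tensors for the arteriole
# and venule compartments (venule twice as permeable), an isotropic unit
# capillary tensor, and capillary couplings strong enough that coupling
# and diffusion terms are balanced.  With the printed exact solutions these
# constants reproduce the reference grid-convergence figures; edit this
# file (or pass an alternative) to re-run the study under perturbed
# parameters.
K:
  - [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]
  - [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
  - [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 2.0]]
beta:
  - [0.0, 10.0, 0.0]
  - [10.0, 0.0, 20.0]
  - [0.0, 20.0, 0.0]
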