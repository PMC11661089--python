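# Default parameterisation of the extended Peyrard-Bishop-Dauxois model
# (canonical two-class values of the established EPBD lineage) and of the
# Langevin thermostat.  Units: eV, Angstrom, amu, ps^-1, K.

d_at        = 0.05      # Morse depth, A-T pair (eV)
d_gc        = 0.075     # Morse depth, G-C pair (eV)
a_at        = 4.2       # Morse inverse width, A-T (1/A)
a_gc        = 6.9       # Morse inverse width, G-C (1/A)
k_stack     = 0.025     # uniform stacking constant (eV/A^2)
                        # per-dinucleotide override: k_stack.AG = ... etc.
rho         = 2.0       # anharmonic stacking strength (dimensionless)
beta_stack  = 0.35      # anharmonic stacking range (1/A)
mass        = 300.0     # base-pair mass (amu)
gamma       = 5.0       # thermostat friction (1/ps)
k_B         = 8.617333262e-5   # Boltzmann constant (eV/K)
temperature = 310.0     # thermostat setpoint (K)
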