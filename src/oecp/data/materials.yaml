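# Material library for coaxial-probe sensing-volume analysis.
#
# Single-pole Debye parameters (eps_static, eps_inf, tau [s]) plus static
# conductivity sigma_static [S/m].  tau = 0 marks a dispersion-free material.
# Reference-liquid parameters are literature values at the stated temperature
# (degrees C); Teflon and the two tissue-mimicking phantom solutions are
# modeled as dispersion-free with their 300 MHz relative permittivity.
materials:
  - name: teflon
    eps_static: 2.1
    eps_inf: 2.1
    tau: 0.0
    sigma_static: 0.0
    temperature: 20.0
    source: "PTFE, dispersion-free over 0.3-1.5 GHz"
  - name: ethanol
    eps_static: 24.35
    eps_inf: 4.48
    tau: 1.63e-10
    sigma_static: 0.0
    temperature: 25.0
    source: "literature Debye fit, 25 C"
  - name: methanol
    eps_static: 33.6
    eps_inf: 5.7
    tau: 5.6e-11
    sigma_static: 0.0
    temperature: 20.0
    source: "literature Debye fit, 20 C"
  - name: deionized_water
    eps_static: 80.2
    eps_inf: 5.6
    tau: 9.36e-12
    sigma_static: 0.0
    temperature: 20.0
    source: "literature Debye fit, 20 C"
  - name: dmso
    eps_static: 47.0
    eps_inf: 47.0
    tau: 0.0
    sigma_static: 0.8
    temperature: 20.0
    source: "muscle-tissue phantom, dispersion-free approximation at 300 MHz"
  - name: sugar_salt_solution
    eps_static: 60.0
    eps_inf: 60.0
    tau: 0.0
    sigma_static: 1.2
    temperature: 20.0
    source: "breast-tumor phantom, dispersion-free approximation at 300 MHz"
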