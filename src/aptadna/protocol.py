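"""Emission of the molecular-dynamics protocol as GROMACS parameter files.

The simulation protocol itself (no MD is executed here) is: solvate in a
triclinic TIP3P box under the CHARMM27 force field, neutralize with Na+/Cl-,
steepest-descent minimization, 100 ps NVT then 100 ps NPT equilibration, and
a 200 ns NPT production run, in duplicate at 300 K and 310 K.  Long-range
electrostatics use PME with 1.2 nm real-space and van der Waals cutoffs;
temperature is coupled with the velocity-rescale (modified Berendsen)
thermostat and pressure with the Parrinello–Rahman barostat at 1 atm.

Coupling constants and the 2 fs timestep are conventional defaults rather
than protocol requirements; emitted files flag them as assumptions in their
header comments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nucleic import AptadnaError

ATM_TO_BAR = 1.01325

STAGES = ("minim", "nvt", "npt", "production")


@dataclass(frozen=True)
class ProtocolSpec:
    """Full parameterization of the simulation protocol."""

    temperatures: tuple[float, ...] = (300.0, 310.0)   # K
    production_ns: float = 200.0
    equil_ps: float = 100.0           # per equilibration stage
    cutoff_nm: float = 1.2            # rvdw = rcoulomb
    timestep_fs: float = 2.0
    electrostatics: str = "PME"
    thermostat: str = "V-rescale"     # the "modified Berendsen" scheme
    barostat: str = "Parrinello-Rahman"
    pressure_atm: float = 1.0
    tau_t_ps: float = 0.1
    tau_p_ps: float = 2.0
    water: str = "TIP3P"
    forcefield: str = "CHARMM27"
    box: str = "triclinic"
    ions: str = "Na+/Cl- to neutrality"
    minimization: str = "steepest descent"
    min_nsteps: int = 50000
    min_emtol: float = 1000.0         # kJ/mol/nm

    def __post_init__(self):
        if any(t <= 0 for t in self.temperatures) or not self.temperatures:
            raise ValueError("temperatures must be positive")
        if self.production_ns <= 0 or self.equil_ps <= 0:
            raise ValueError("durations must be positive")
        if self.cutoff_nm <= 0 or self.timestep_fs <= 0:
            raise ValueError("cutoff and timestep must be positive")

    def nsteps(self, stage: str) -> int:
        """Step count so that steps × timestep equals the stage duration."""
        if stage == "minim":
            return self.min_nsteps
        duration_fs = (
            self.production_ns * 1e6 if stage == "production"
            else self.equil_ps * 1e3
        )
        steps = duration_fs / self.timestep_fs
        if abs(steps - round(steps)) > 1e-9:
            raise AptadnaError(
                f"{stage} duration is not a multiple of the timestep"
            )
        return int(round(steps))


def emit_mdp(
    spec: ProtocolSpec, stage: str, temperature: float | None = None
) -> str:
    """GROMACS .mdp parameter text for one stage of the protocol.

    ``temperature`` defaults to the first entry of ``spec.temperatures``;
    it is ignored for the minimization stage.  Output is byte-identical for
    identical inputs.
    """
    if stage not in STAGES:
        raise AptadnaError(f"unknown stage {stage!r}; choose from {STAGES}")
    if temperature is None:
        temperature = spec.temperatures[0]

    nsteps = spec.nsteps(stage)
    dt_ps = spec.timestep_fs / 1000.0
    lines = [
        f"; {stage} stage — ss-aptamer conversion protocol",
        f"; force field {spec.forcefield} + {spec.water} water, "
        f"{spec.box} box, {spec.ions}",
        "; ASSUMED (not protocol-specified): timestep "
        f"{spec.timestep_fs:g} fs, tau_t {spec.tau_t_ps:g} ps, "
        f"tau_p {spec.tau_p_ps:g} ps",
        "",
    ]
    if stage == "minim":
        lines += [
            "integrator               = steep",
            f"emtol                    = {spec.min_emtol:g}",
            "emstep                   = 0.01",
            f"nsteps                   = {nsteps}",
        ]
    else:
        lines += [
            "integrator               = md",
            f"dt                       = {dt_ps:g}",
            f"nsteps                   = {nsteps}",
        ]
    lines += [
        "cutoff-scheme            = Verlet",
        f"rcoulomb                 = {spec.cutoff_nm:g}",
        f"rvdw                     = {spec.cutoff_nm:g}",
        f"coulombtype              = {spec.electrostatics}",
        "pbc                      = xyz",
    ]
    if stage != "minim":
        lines += [
            "constraints              = h-bonds",
            "constraint-algorithm     = lincs",
            f"tcoupl                   = {spec.thermostat}",
            "tc-grps                  = System",
            f"tau_t                    = {spec.tau_t_ps:g}",
            f"ref_t                    = {temperature:g}",
        ]
    if stage in ("npt", "production"):
        lines += [
            f"pcoupl                   = {spec.barostat}",
            "pcoupltype               = isotropic",
            f"tau_p                    = {spec.tau_p_ps:g}",
            f"ref_p                    = {spec.pressure_atm * ATM_TO_BAR:g}",
            "compressibility          = 4.5e-05",
        ]
    else:
        lines += ["pcoupl                   = no"]
    if stage == "nvt":
        lines += [
            "gen_vel                  = yes",
            f"gen_temp                 = {temperature:g}",
            "gen_seed                 = -1",
        ]
    return "\n".join(lines) + "\n"


_STAGE_FILES = {
    "minim": "minim.mdp",
    "nvt": "nvt.mdp",
    "npt": "npt.mdp",
    "production": "production.mdp",
}


def emit_run_plan(spec: ProtocolSpec, molecule: str = "aptamer") -> str:
    """Human-readable ordered run plan naming the emitted .mdp files."""
    temps = ", ".join(f"{t:g} K" for t in spec.temperatures)
    lines = [
        f"# MD run plan — {molecule}",
        "",
        f"Independent runs: one per temperature ({temps}); each system is "
        "simulated in duplicate, with temperature as the sole experimental "
        "variable.",
        "",
        f"1. Build the {spec.box} simulation box and solvate with "
        f"{spec.water} water ({spec.forcefield} force field).",
        f"2. Add counterions ({spec.ions}).",
        f"3. Energy-minimize with the {spec.minimization} algorithm "
        f"({_STAGE_FILES['minim']}).",
        f"4. NVT equilibration, {spec.equil_ps:g} ps "
        f"({_STAGE_FILES['nvt']}; {spec.thermostat} thermostat).",
        f"5. NPT equilibration, {spec.equil_ps:g} ps "
        f"({_STAGE_FILES['npt']}; {spec.barostat} barostat, "
        f"{spec.pressure_atm:g} atm).",
        f"6. Production, {spec.production_ns:g} ns under NPT "
        f"({_STAGE_FILES['production']}; {spec.electrostatics} "
        f"electrostatics, {spec.cutoff_nm:g} nm cutoffs).",
        "7. Post-dynamics analysis: superposition RMSD against the reference "
        "structure and intramolecular hydrogen-bond counts over the "
        "trajectory.",
        "",
        "Each .mdp file is instantiated once per temperature "
        f"(ref_t/gen_temp set to each of {temps}).",
    ]
    return "\n".join(lines) + "\n"
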