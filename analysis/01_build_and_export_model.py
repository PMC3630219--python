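"""Build the hMEC ErbB reconstruction, check its invariants, and export
it in both interchange formats.

Writes results/model/hmec.rules and results/model/hmec.sbml and prints a
structural summary.
"""

from pathlib import Path

from erbbsim.hmec import build_hmec_mini, trafficking_subchain
from erbbsim.io import model_hash, write_rule_file, write_sbml_qual
from erbbsim.logic import validate_network

OUT = Path(__file__).resolve().parent.parent / "results" / "model"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    net = build_hmec_mini()
    violations = validate_network(net)
    print(f"hMEC reconstruction: {len(net.internals)} internal nodes, "
          f"{len(net.externals)} external inputs, hash {model_hash(net)}")
    print(f"validation violations: {violations or 'none'}")
    sub = trafficking_subchain()
    print(f"EGF trafficking subchain: {len(sub.internals)} internal, "
          f"boundary inputs {sorted(sub.externals)}")
    write_rule_file(net, OUT / "hmec.rules")
    write_sbml_qual(net, OUT / "hmec.sbml")
    print(f"wrote {OUT / 'hmec.rules'} and {OUT / 'hmec.sbml'}")


if __name__ == "__main__":
    main()
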