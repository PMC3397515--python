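>right_handed_state synthetic stand-in sequence; the right- and left-handed filament states are conformations of the same protein, so the two records are identical by construction
MSDLKERAEAGIQTVDELLGGGFERGSITEIFGEFGSGKTQLAHTLAVMVQLPPEEGGLN
GSVMWIDTENTFRPERIKEIAQNRGLDPDEVLKHIYVARAFNSNHQMELVEQAEDLIKEL
>left_handed_state synthetic stand-in sequence; identical to the right-handed record by construction
MSDLKERAEAGIQTVDELLGGGFERGSITEIFGEFGSGKTQLAHTLAVMVQLPPEEGGLN
GSVMWIDTENTFRPERIKEIAQNRGLDPDEVLKHIYVARAFNSNHQMELVEQAEDLIKEL
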