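# label <TAB> category <TAB> template
defect	plain	{fppron} {child} has {term} and is doing great
defect	plain	{fppron} {child} was born with {term} and is the strongest {child} ever
defect	plain	so blessed to call this {term} warrior {fppron} {child}
defect	plain	{fppron} {child} had surgery for {term} today and did amazing
defect	plain	proud of {fppron} brave {child} fighting {term} every single day
defect	implicit	{fppron} little miracle. {term}, two surgeries, still smiling
defect	implicit	{fppron} sweet {child}. {term} and the happiest smile you ever saw
defect	implicit	one year home from the hospital. {term}. {fppron} hero
defect	hashtag_fused	{fppron} #{fused_term} #cutie
defect	hashtag_fused	her face #lovemygirl #{fused_term} #motheranddaughter
defect	hashtag_fused	so proud #{fused_term} warrior #momlife
defect	modifier	{fppron} unborn {child} was diagnosed with {term} last week
defect	modifier	{fppron} precious little {child} has {term} and we would not change a thing
possible_defect	name	{name} was diagnosed with {term} and had surgery to repair it
possible_defect	name	scheduling an appointment for {name} to confirm a {term} diagnosis
possible_defect	name	praying for {name} as the doctors check for {term}
possible_defect	pronoun	he has {term} but i dont think he is special needs
possible_defect	pronoun	she may have {term} the doctors are not sure yet
possible_defect	pronoun	so in love with this little boy. {term} and he survived
possible_defect	hedge	the doctor said it could be {term}
possible_defect	hedge	waiting on results. it might be {term}
possible_defect	hedge	ultrasound today. possible {term} they said
non_defect	reported	{name} says my {child} has {term} but i would not want to live in a world without it
non_defect	reported	interview: {name} opens up about parenting a {child} with {term}
non_defect	reported	watch: this mom shares what life is like when your {child} has {term}
non_defect	fundraiser	please donate to help children with {term}
non_defect	fundraiser	join our walk this weekend to support families facing {term}
non_defect	fundraiser	help us fund new research into {term} every dollar counts
non_defect	headline	new study links {term} to genetic factors scientists say
non_defect	headline	hospital opens new clinic for children with {term}
non_defect	headline	lawmakers debate coverage for {term} treatment
non_defect	headline	scientists report progress toward understanding {term}
non_defect	other	today is {term} awareness day wear blue
non_defect	other	did you know {term} affects thousands of newborns each year
non_defect	other	learn the facts about {term} this awareness month
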