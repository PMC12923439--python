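ain't	is not
aren't	are not
arent	are not
can't	can not
cannot	can not
cant	can not
could've	could have
couldn't	could not
couldnt	could not
couldve	could have
daren't	dare not
didn't	did not
didnt	did not
doesn't	does not
doesnt	does not
don't	do not
dont	do not
gimme	give me
gonna	going to
gotta	got to
hadn't	had not
hadnt	had not
hasn't	has not
hasnt	has not
haven't	have not
havent	have not
he'd	he would
he'll	he will
he's	he is
here'd	here would
here'll	here will
here's	here is
heres	here is
how'd	how would
how'll	how will
how's	how is
i'd	i would
i'll	i will
i'm	i am
i've	i have
im	i am
isn't	is not
isnt	is not
it'd	it would
it'll	it will
it's	it is
ive	i have
kinda	kind of
lemme	let me
let's	let us
ma'am	madam
might've	might have
mightn't	might not
must've	must have
mustn't	must not
mustnt	must not
needn't	need not
o'clock	oclock
oughtn't	ought not
shan't	shall not
she'd	she would
she'll	she will
she's	she is
should've	should have
shouldn't	should not
shouldnt	should not
shouldve	should have
sorta	sort of
that'd	that would
that'll	that will
that's	that is
thats	that is
there'd	there would
there'll	there will
there's	there is
theres	there is
they'd	they would
they'll	they will
they're	they are
they've	they have
theyd	they would
theyll	they will
theyre	they are
theyve	they have
wanna	want to
wasn't	was not
wasnt	was not
we'd	we would
we'll	we will
we're	we are
we've	we have
weren't	were not
werent	were not
weve	we have
what'd	what would
what'll	what will
what's	what is
whats	what is
when'd	when would
when'll	when will
when's	when is
where'd	where would
where'll	where will
where's	where is
wheres	where is
who'd	who would
who'll	who will
who's	who is
won't	will not
wont	will not
would've	would have
wouldn't	would not
wouldnt	would not
wouldve	would have
y'all	you all
yall	you all
you'd	you would
you'll	you will
you're	you are
you've	you have
youd	you would
youll	you will
youre	you are
youve	you have
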