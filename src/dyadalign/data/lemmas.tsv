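am	be
answered	answer
answering	answer
answers	answer
are	be
arms	arm
asked	ask
asking	ask
asks	ask
ate	eat
babies	baby
bags	bag
beaches	beach
became	become
become	become
becomes	become
becoming	become
bedrooms	bedroom
been	be
began	begin
begining	begin
begins	begin
begun	begin
being	be
bes	be
best	good
better	good
bigger	big
biggest	big
bing	be
birds	bird
boats	boat
bodies	body
books	book
bottles	bottle
bought	buy
boxes	box
bridges	bridge
brighter	bright
brightest	bright
bringing	bring
brings	bring
brothers	brother
brought	bring
building	build
builds	build
built	build
buying	buy
buys	buy
called	call
calling	call
calls	call
came	come
carried	carry
carries	carry
carrying	carry
cars	car
catches	catch
catching	catch
cats	cat
caught	catch
chairs	chair
children	child
chooses	choose
choosing	choose
chose	choose
chosen	choose
cities	city
cleaned	clean
cleaning	clean
cleans	clean
climbed	climb
climbing	climb
climbs	climb
closed	close
closes	close
closing	close
clouds	cloud
coats	coat
colder	cold
coldest	cold
come	come
comes	come
coming	come
cooked	cook
cooking	cook
cooks	cook
cows	cow
cried	cry
cries	cry
crossed	cross
crosses	cross
crossing	cross
crying	cry
cups	cup
danced	dance
dances	dance
dancing	dance
darker	dark
darkest	dark
did	do
died	die
dies	die
diing	die
doctors	doctor
does	do
dogs	dog
doing	do
done	do
doors	door
drank	drink
drawing	draw
drawn	draw
draws	draw
dreams	dream
drew	draw
drinking	drink
drinks	drink
driven	drive
drives	drive
driving	drive
drove	drive
drunk	drink
easier	easy
easiest	easy
eaten	eat
eating	eat
eats	eat
enjoyed	enjoy
enjoying	enjoy
enjoys	enjoy
eyes	eye
faces	face
fallen	fall
falling	fall
falls	fall
families	family
farms	farm
fathers	father
feeling	feel
feels	feel
feet	foot
fell	fall
felt	feel
fields	field
finding	find
finds	find
fingers	finger
fishes	fish
flew	fly
flies	fly
flowers	flower
flown	fly
flying	fly
followed	follow
following	follow
follows	follow
forests	forest
forgeting	forget
forgets	forget
forgot	forget
forgotten	forget
forks	fork
found	find
friends	friend
games	game
gardens	garden
gave	give
geese	goose
geting	get
gets	get
gifts	gift
given	give
gives	give
giving	give
glasses	glass
goes	go
going	go
gone	go
got	get
gotten	get
grew	grow
growing	grow
grown	grow
grows	grow
had	have
halves	half
hands	hand
happened	happen
happening	happen
happens	happen
happier	happy
happiest	happy
harder	hard
hardest	hard
has	have
hated	hate
hates	hate
hating	hate
hats	hat
haves	have
having	have
heads	head
heard	hear
hearing	hear
hears	hear
hearts	heart
held	hold
helped	help
helping	help
helps	help
holding	hold
holds	hold
hoped	hope
hopes	hope
hoping	hope
horses	horse
hours	hour
houses	house
hurried	hurry
hurries	hurry
hurrying	hurry
ideas	idea
is	be
joined	join
joining	join
joins	join
jumped	jump
jumping	jump
jumps	jump
keeping	keep
keeps	keep
kept	keep
kicked	kick
kicking	kick
kicks	kick
killed	kill
killing	kill
kills	kill
kitchens	kitchen
knew	know
knifes	knife
knives	knife
knocked	knock
knocking	knock
knocks	knock
knowing	know
known	know
knows	know
landed	land
landing	land
lands	land
laughed	laugh
laughing	laugh
laughs	laugh
learned	learn
learning	learn
learns	learn
leaves	leave
leaving	leave
left	leave
legs	leg
letters	letter
lifted	lift
lifting	lift
lifts	lift
liked	like
likes	like
liking	like
listened	listen
listening	listen
listens	listen
lived	live
lives	life
living	live
longer	long
longest	long
looked	look
looking	look
looks	look
loses	lose
losing	lose
lost	lose
loved	love
loves	love
loving	love
made	make
makes	make
making	make
marched	march
marches	march
marching	march
markets	market
meaning	mean
means	mean
meant	mean
meeting	meet
meets	meet
men	man
met	meet
mice	mouse
minds	mind
minutes	minute
missed	miss
misses	miss
missing	miss
moments	moment
months	month
moons	moon
mornings	morning
mothers	mother
mountains	mountain
moved	move
moves	move
movies	movie
moving	move
needed	need
needing	need
needs	need
nights	night
noticed	notice
notices	notice
noticing	notice
oceans	ocean
offices	office
older	old
oldest	old
opened	open
opening	open
opens	open
paid	pay
painted	paint
painting	paint
paints	paint
parties	party
paying	pay
pays	pay
people	person
picked	pick
picking	pick
picks	pick
pictures	picture
planes	plane
planted	plant
planting	plant
plants	plant
plates	plate
played	play
playing	play
plays	play
pointed	point
pointing	point
points	point
problems	problem
pulled	pull
pulling	pull
pulls	pull
pushed	push
pushes	push
pushing	push
questions	question
rained	rain
raining	rain
rains	rain
ran	run
rang	ring
reached	reach
reaches	reach
reaching	reach
read	read
reading	read
reads	read
remembered	remember
remembering	remember
remembers	remember
rested	rest
resting	rest
rests	rest
ridden	ride
rides	ride
riding	ride
ringing	ring
rings	ring
risen	rise
rises	rise
rising	rise
rivers	river
roads	road
rode	ride
rose	rise
run	run
rung	ring
runing	run
runs	run
sadder	sad
saddest	sad
said	say
sang	sing
sat	sit
saved	save
saves	save
saving	save
saw	see
saying	say
says	say
schools	school
seeing	see
seemed	seem
seeming	seem
seems	seem
seen	see
sees	see
selling	sell
sells	sell
sending	send
sends	send
sent	send
shared	share
shares	share
sharing	share
shirts	shirt
shoes	shoe
shorter	short
shortest	short
shoulders	shoulder
shouted	shout
shouting	shout
shouts	shout
showed	show
showing	show
shows	show
singing	sing
sings	sing
sisters	sister
siting	sit
sits	sit
sleeping	sleep
sleeps	sleep
slept	sleep
smaller	small
smallest	small
smelled	smell
smelling	smell
smells	smell
smiled	smile
smiles	smile
smiling	smile
snowed	snow
snowing	snow
snows	snow
sold	sell
songs	song
sounded	sound
sounding	sound
sounds	sound
speaking	speak
speaks	speak
spending	spend
spends	spend
spent	spend
spoke	speak
spoken	speak
spoons	spoon
standing	stand
stands	stand
stared	stare
stares	stare
staring	stare
stars	star
started	start
starting	start
starts	start
stayed	stay
staying	stay
stays	stay
stones	stone
stood	stand
stoped	stop
stoping	stop
stops	stop
stores	store
stories	story
students	student
studied	study
studies	study
studying	study
sung	sing
suns	sun
swam	swim
swiming	swim
swims	swim
swum	swim
tables	table
taken	take
takes	take
taking	take
talked	talk
talking	talk
talks	talk
taller	tall
tallest	tall
tasted	taste
tastes	taste
tasting	taste
taught	teach
teachers	teacher
teaches	teach
teaching	teach
teeth	tooth
telling	tell
tells	tell
thanked	thank
thanking	thank
thanks	thank
thinking	think
thinks	think
thought	think
threw	throw
throwing	throw
thrown	throw
throws	throw
tickets	ticket
told	tell
took	take
touched	touch
touches	touch
touching	touch
towns	town
trained	train
training	train
trains	train
traveled	travel
traveling	travel
travels	travel
treated	treat
treating	treat
treats	treat
trees	tree
tried	try
tries	try
trusted	trust
trusting	trust
trusts	trust
trying	try
turned	turn
turning	turn
turns	turn
understanding	understand
understands	understand
understood	understand
used	use
uses	use
using	use
visited	visit
visiting	visit
visits	visit
voices	voice
waited	wait
waiting	wait
waits	wait
wakes	wake
waking	wake
walked	walk
walking	walk
walks	walk
wanted	want
wanting	want
wants	want
warmer	warm
warmest	warm
was	be
washed	wash
washes	wash
washing	wash
watched	watch
watches	watch
watching	watch
wearing	wear
wears	wear
weeks	week
went	go
were	be
whispered	whisper
whispering	whisper
whispers	whisper
windows	window
wining	win
wins	win
wished	wish
wishes	wish
wishing	wish
wives	wife
woke	wake
woken	wake
wolves	wolf
women	woman
won	win
wondered	wonder
wondering	wonder
wonders	wonder
words	word
wore	wear
worked	work
working	work
works	work
worn	wear
worried	worry
worries	worry
worrying	worry
worse	bad
worst	bad
writes	write
writing	write
written	write
wrote	write
years	year
younger	young
youngest	young
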