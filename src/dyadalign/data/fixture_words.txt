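afraid
angry
answer
arm
ask
baby
bad
bag
be
beach
beautiful
become
bedroom
begin
big
bird
bitter
boat
body
book
bottle
box
brave
bridge
bright
bring
brother
build
buy
call
calm
car
carry
cat
catch
chair
child
choose
city
clean
climb
close
cloud
coat
cold
come
cook
cow
cross
cry
cup
curious
dance
dark
deep
die
do
doctor
dog
door
draw
dream
drink
drive
easy
eat
empty
enjoy
eye
face
fall
family
farm
fast
father
feel
field
fierce
find
finger
fish
flower
fly
follow
foot
forest
forget
fork
friend
full
funny
game
garden
gentle
get
gift
give
glass
go
good
goose
grow
half
hand
happen
happy
hard
hat
hate
have
head
hear
heart
heavy
help
hold
hope
horse
hour
house
hungry
hurry
idea
join
jump
keep
kick
kill
kitchen
knife
knock
know
land
laugh
leaf
learn
leave
leg
letter
life
lift
light
like
listen
live
lonely
long
look
lose
loud
love
make
man
march
market
mean
meet
mind
minute
miss
moment
month
moon
morning
mother
mountain
mouse
move
movie
need
night
notice
ocean
office
old
open
paint
party
pay
person
pick
picture
plane
plant
plate
play
point
poor
problem
proud
pull
push
question
quiet
rain
reach
read
remember
rest
rich
ride
ring
rise
river
road
run
sad
save
say
school
see
seem
sell
send
serious
shallow
share
shirt
shoe
short
shoulder
shout
show
sing
sister
sit
sleep
slow
small
smell
smile
snow
soft
song
sound
speak
spend
spoon
stand
star
stare
start
stay
stone
stop
store
story
strange
strong
student
study
sun
sweet
swim
table
take
talk
tall
taste
teach
teacher
tell
thank
think
thirsty
throw
ticket
tired
tooth
touch
town
train
travel
treat
tree
trust
try
turn
ugly
understand
use
visit
voice
wait
wake
walk
want
warm
wash
watch
weak
wear
week
whisper
wife
win
window
wish
wolf
woman
wonder
word
work
worry
write
year
young
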